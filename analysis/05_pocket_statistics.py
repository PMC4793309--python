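#!/usr/bin/env python
"""Describe the binding pockets of the funnel's final targets.

Reads results/funnel/pocket_stats.json (written by 03_run_funnel.py) and
prints pocket sizes, the pooled residue composition with the most-used amino
acids, the hydrogen-bond fraction, and the K/S/T acetylation-candidate screen.
"""

import argparse
import json
from pathlib import Path


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--stats", type=Path, default=Path("results/funnel/pocket_stats.json"))
    args = ap.parse_args()

    if not args.stats.exists():
        raise SystemExit("run analysis/03_run_funnel.py first")
    stats = json.loads(args.stats.read_text())

    sizes = stats["pocket_sizes"]
    print(f"{stats['n_pockets']} pockets, sizes {min(sizes)}-{max(sizes)} residues")
    comp = stats["composition"]
    top = sorted(comp.items(), key=lambda kv: -kv[1])[:8]
    print("most used amino acids:", ", ".join(f"{c} ({n})" for c, n in top))
    print(f"pockets forming H-bonds with the ligand: {stats['hbond_fraction']:.0%}")
    print(f"pockets with a possible acetylation site (K/S/T): "
          f"{stats['n_with_acetylation_site']}/{stats['n_pockets']} "
          f"({stats['acetylation_fraction']:.0%})")


if __name__ == "__main__":
    main()
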