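#!/usr/bin/env python
"""Generate the planted-pocket benchmark as plain PDB fixtures.

Builds a synthetic query complex (pocket shell around the toy
acetylsalicylate-like ligand), extracts its 5 Å binding site, and writes a
110-structure database — 10 decoys carrying a planted, noise-perturbed copy
of the site (sigma = 0.3 Å, one BLOSUM62-compatible substitution) among 100
clean decoys — plus the ground-truth table, under results/benchmark/.
"""

import argparse
import json
from pathlib import Path

import pocketfish as pf
from pocketfish import synth


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--outdir", type=Path, default=Path("results/benchmark"))
    args = ap.parse_args()

    outdir = args.outdir
    (outdir / "structures").mkdir(parents=True, exist_ok=True)

    query = pf.make_query_complex(args.seed, struct_id="QUERY")
    ligand = query.ligands[0]
    site = pf.extract_site(query, ligand)
    pf.write_pdb(query, outdir / "query_complex.pdb")
    pf.sites.write_site_table(site, ligand, outdir / "query_site.tsv")

    spec = synth.PlantSpec(noise_sigma=0.3, n_substitutions=1, seed=args.seed + 1)
    pocket_dir = ligand.heavy_coords().mean(axis=0) - site.rep_coords.mean(axis=0)
    db, truth = pf.make_benchmark(
        site, n_planted=10, n_decoys=100, spec=spec,
        pocket_direction=pocket_dir, ligand_coords=ligand.heavy_coords(),
    )
    for s in db:
        pf.write_pdb(s, outdir / "structures" / f"{s.struct_id}.pdb")
    truth.to_json(outdir / "truth.json")
    pf.structures.write_manifest(db, outdir / "manifest.tsv")

    print(f"query site: {site.size} residues ({site.codes}) within {site.cutoff} Å")
    print(f"database: {len(db)} structures, {len(truth.planted_ids)} planted")
    print(f"wrote PDB fixtures and truth table under {outdir}/")


if __name__ == "__main__":
    main()
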