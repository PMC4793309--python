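"""Descriptive statistics over predicted binding pockets.

Pocket membership uses the same 5 Å heavy-atom rule as site extraction, so one
definition serves both the search and the statistics.  The acetylation screen
asks whether a pocket contains at least one residue whose side chain can in
principle be acetylated (lysine, serine, threonine).
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from .sites import BindingSite
from .structures import THREE_TO_ONE

ACETYLATABLE = {"LYS", "SER", "THR"}


@dataclass
class PocketProfile:
    target_id: str
    residues: list[tuple[str, str, int]]  # (res_name, chain, seq_id)
    formed_hbond: bool = False

    @property
    def size(self) -> int:
        return len(self.residues)

    @property
    def has_KST(self) -> bool:
        return any(name in ACETYLATABLE for name, _, _ in self.residues)

    @classmethod
    def from_site(cls, site: BindingSite, target_id: str | None = None,
                  formed_hbond: bool = False) -> "PocketProfile":
        return cls(
            target_id=target_id or site.source_struct,
            residues=[(r.res_name, r.chain_id, r.seq_id) for r in site.residues],
            formed_hbond=formed_hbond,
        )


@dataclass
class CompositionTable:
    counts: dict[str, int]
    n_pockets: int

    def frequent(self, threshold: int = 20) -> list[str]:
        """One-letter codes occurring more than *threshold* times, by count desc."""
        return sorted(
            (c for c, n in self.counts.items() if n > threshold),
            key=lambda c: (-self.counts[c], c),
        )


def composition(pockets: Sequence[PocketProfile]) -> CompositionTable:
    """Per-amino-acid occurrence counts pooled over all pockets."""
    if not pockets:
        raise ValueError("no pockets")
    counter: Counter[str] = Counter()
    for p in pockets:
        counter.update(THREE_TO_ONE.get(name, "X") for name, _, _ in p.residues)
    return CompositionTable(counts=dict(counter), n_pockets=len(pockets))


def acetylation_screen(pockets: Sequence[PocketProfile]) -> tuple[int, float]:
    """(#pockets containing ≥1 of K/S/T, fraction of all pockets)."""
    if not pockets:
        raise ValueError("no pockets")
    n = sum(1 for p in pockets if p.has_KST)
    return n, n / len(pockets)


def hbond_fraction(profiles: Sequence[PocketProfile]) -> float:
    """Fraction of pockets whose pose formed at least one hydrogen bond."""
    if not profiles:
        raise ValueError("no pockets")
    return sum(1 for p in profiles if p.formed_hbond) / len(profiles)


def read_pocket_table(path: str | Path) -> list[PocketProfile]:
    """Read pocket residue lists from TSV (target_id, res_name, chain, seq_id[, formed_hbond])."""
    pockets: dict[str, PocketProfile] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {name: k for k, name in enumerate(header)}
        for line in fh:
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            tid = f[idx["target_id"]]
            if tid not in pockets:
                hb = bool(int(f[idx["formed_hbond"]])) if "formed_hbond" in idx else False
                pockets[tid] = PocketProfile(target_id=tid, residues=[], formed_hbond=hb)
            pockets[tid].residues.append(
                (f[idx["res_name"]].upper(), f[idx["chain"]], int(f[idx["seq_id"]]))
            )
    return list(pockets.values())


def write_stats_report(pockets: Sequence[PocketProfile], path: str | Path,
                       frequent_threshold: int = 20) -> dict:
    comp = composition(pockets)
    n_kst, frac_kst = acetylation_screen(pockets)
    report = {
        "n_pockets": comp.n_pockets,
        "pocket_sizes": sorted(p.size for p in pockets),
        "composition": dict(sorted(comp.counts.items())),
        "frequent_residues": comp.frequent(frequent_threshold),
        "n_with_acetylation_site": n_kst,
        "acetylation_fraction": frac_kst,
        "hbond_fraction": hbond_fraction(pockets),
    }
    Path(path).write_text(json.dumps(report, indent=2) + "\n")
    return report
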