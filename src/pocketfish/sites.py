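"""Ligand binding-site extraction, contact matrices, and the query set.

A binding site is the set of residues whose heavy atoms come within a distance
cutoff (default 5 Å) of any heavy atom of the bound ligand.  Sites are
summarised by one representative atom per residue (Cα by default) and compared
through their contact matrix — the symmetric matrix of pairwise
representative-atom distances, which is invariant under rigid motion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import yaml
from scipy.spatial.distance import cdist, squareform, pdist

from .structures import Residue, Structure


class SiteError(ValueError):
    pass


@dataclass
class BindingSite:
    site_id: str
    source_struct: str
    ligand_name: str
    residues: list[Residue]
    rep_coords: np.ndarray  # (n, 3) Å
    cutoff: float

    def __post_init__(self) -> None:
        self.rep_coords = np.asarray(self.rep_coords, dtype=float)
        if len(self.residues) < 3:
            raise SiteError(f"site {self.site_id}: fewer than 3 residues")
        if self.rep_coords.shape != (len(self.residues), 3):
            raise SiteError(f"site {self.site_id}: rep_coords shape mismatch")

    @property
    def size(self) -> int:
        return len(self.residues)

    @property
    def codes(self) -> str:
        """One-letter residue codes in site order."""
        return "".join(r.one_letter for r in self.residues)


@dataclass
class ContactMatrix:
    dist: np.ndarray  # (n, n) Å
    labels: str

    def __post_init__(self) -> None:
        self.dist = np.asarray(self.dist, dtype=float)
        n = self.dist.shape[0]
        if self.dist.shape != (n, n) or len(self.labels) != n:
            raise ValueError("contact matrix must be square with matching labels")
        if not np.allclose(self.dist, self.dist.T, atol=1e-6):
            raise ValueError("contact matrix must be symmetric")
        if np.any(np.diag(self.dist) != 0) or np.any(self.dist < 0):
            raise ValueError("contact matrix needs a zero diagonal and non-negative entries")


@dataclass
class QueryComplex:
    struct_id: str
    family: str
    site: BindingSite
    ligand: Residue

    def __post_init__(self) -> None:
        if not self.family:
            raise ValueError("family label required")
        if not self.ligand.atoms:
            raise ValueError("ligand is empty")


@dataclass
class QueryEntry:
    """One row of the query-set configuration (no structure attached yet)."""
    struct_id: str
    ligand_name: str
    family: str


def extract_site(
    structure: Structure,
    ligand: Residue,
    cutoff: float = 5.0,
    rep_atom: str = "CA",
    site_id: str | None = None,
) -> BindingSite:
    """Residues with any heavy atom within *cutoff* Å of a ligand heavy atom.

    Residues are returned in chain order; representative coordinates are the
    named *rep_atom* (Cα by default, Cβ via ``rep_atom="CB"``; residues lacking
    the representative atom fall back to Cα).
    """
    if cutoff <= 0:
        raise SiteError("cutoff must be positive")
    lig_xyz = ligand.heavy_coords()
    if lig_xyz.size == 0:
        raise SiteError("ligand has no heavy atoms")

    members: list[Residue] = []
    reps: list[np.ndarray] = []
    for res in structure.residues:
        xyz = res.heavy_coords()
        if xyz.size == 0:
            continue
        if cdist(xyz, lig_xyz).min() <= cutoff:
            rep = res.atom(rep_atom) or res.ca
            members.append(res)
            reps.append(rep.coord)
    if len(members) < 3:
        raise SiteError(
            f"only {len(members)} residues within {cutoff} Å of {ligand.res_name}"
        )
    return BindingSite(
        site_id=site_id or f"{structure.struct_id}:{ligand.res_name}",
        source_struct=structure.struct_id,
        ligand_name=ligand.res_name,
        residues=members,
        rep_coords=np.array(reps),
        cutoff=cutoff,
    )


def contact_matrix(site: BindingSite) -> ContactMatrix:
    """Pairwise representative-atom distance matrix of the site."""
    d = squareform(pdist(site.rep_coords))
    return ContactMatrix(dist=d, labels=site.codes)


def min_ligand_distances(site: BindingSite, ligand: Residue) -> np.ndarray:
    """Per-residue minimum heavy-atom distance to the ligand (for TSV export)."""
    lig = ligand.heavy_coords()
    return np.array([cdist(r.heavy_coords(), lig).min() for r in site.residues])


def write_site_table(site: BindingSite, ligand: Residue, path: str | Path) -> None:
    dmin = min_ligand_distances(site, ligand)
    with open(path, "w") as fh:
        fh.write("site_id\tstruct_id\tchain\tseq_id\tres_name\tmin_dist_to_ligand\n")
        for res, d in zip(site.residues, dmin):
            fh.write(
                f"{site.site_id}\t{site.source_struct}\t{res.chain_id}\t"
                f"{res.seq_id}\t{res.res_name}\t{d:.3f}\n"
            )


def build_query_set(complexes: Sequence) -> list:
    """Reduce query complexes to one representative per protein family.

    Keeps the first-listed entry of each family, preserving order — the
    packaged configuration lists the preferred member of each redundant pair
    first.  Works on any records with ``struct_id`` and ``family`` attributes.
    """
    seen_ids = set()
    seen_families = set()
    kept = []
    for c in complexes:
        if c.struct_id in seen_ids:
            raise ValueError(f"duplicate struct_id {c.struct_id}")
        seen_ids.add(c.struct_id)
        if c.family not in seen_families:
            seen_families.add(c.family)
            kept.append(c)
    return kept


def load_query_config(path: str | Path) -> list[QueryEntry]:
    """Read the YAML query-set configuration (struct_id, ligand, family)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return [
        QueryEntry(struct_id=e["struct_id"], ligand_name=e["ligand"], family=e["family"])
        for e in raw["complexes"]
    ]


def packaged_query_config() -> Path:
    from importlib.resources import files

    return Path(str(files("pocketfish.data") / "query_complexes.yaml"))
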