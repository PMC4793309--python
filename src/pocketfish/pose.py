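"""Geometric docking gate: template-pose transplantation and steric screening.

A matched site carries the rigid transform that superposes the query site onto
the target; applying the same transform to the query's bound ligand places a
template pose in the target pocket.  The gate then accepts or rejects the
target on two counts over protein heavy atoms: clashes (atoms closer than
``clash_dist`` to any ligand atom) and contacts (atoms within
``contact_dist``).  Hydrogen bonds are detected by a distance-only N/O
criterion, since most crystal structures lack hydrogens.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .search import SiteMatch
from .sites import BindingSite
from .structures import Atom, Residue, Structure

POLAR_ELEMENTS = {"N", "O"}


@dataclass
class LigandPose:
    ligand_name: str
    atoms: list[Atom]             # heavy atoms, target frame
    source_match: SiteMatch | None = None

    def coords(self) -> np.ndarray:
        return np.array([a.coord for a in self.atoms])


@dataclass
class HBond:
    ligand_atom: str
    protein_atom: str
    protein_residue: str
    distance: float


@dataclass
class ScreenResult:
    passed: bool
    n_clashes: int
    n_contacts: int
    hbonds: list[HBond] = field(default_factory=list)


def transplant_pose(match: SiteMatch, template_ligand: Residue) -> LigandPose:
    """Map the query's ligand heavy atoms into the target frame via the match transform."""
    atoms = [
        Atom(name=a.name, element=a.element, coord=match.transform.apply(a.coord))
        for a in template_ligand.heavy_atoms()
    ]
    return LigandPose(ligand_name=template_ligand.res_name, atoms=atoms, source_match=match)


def steric_screen(
    pose: LigandPose,
    target: Structure,
    clash_dist: float = 2.2,
    contact_dist: float = 4.5,
    max_clashes: int = 0,
    min_contacts: int = 3,
) -> ScreenResult:
    """Count clashes and contacts of the pose against all protein heavy atoms.

    passed ⇔ n_clashes ≤ max_clashes and n_contacts ≥ min_contacts.
    """
    prot = target.heavy_coords()
    if prot.size == 0:
        raise ValueError(f"{target.struct_id}: structure has no protein heavy atoms")
    d = cdist(prot, pose.coords()).min(axis=1)
    n_clashes = int(np.sum(d < clash_dist))
    n_contacts = int(np.sum(d <= contact_dist))
    return ScreenResult(
        passed=(n_clashes <= max_clashes and n_contacts >= min_contacts),
        n_clashes=n_clashes,
        n_contacts=n_contacts,
    )


def detect_hbonds(
    pose: LigandPose,
    site: BindingSite,
    d_max: float = 3.5,
) -> list[HBond]:
    """Distance-only hydrogen bonds: ligand N/O vs site-residue N/O pairs ≤ d_max Å."""
    lig = [(a.name, a.coord) for a in pose.atoms if a.element.upper() in POLAR_ELEMENTS]
    out: list[HBond] = []
    for res in site.residues:
        for pa in res.heavy_atoms():
            if pa.element.upper() not in POLAR_ELEMENTS:
                continue
            for lname, lcoord in lig:
                dist = float(np.linalg.norm(lcoord - pa.coord))
                if dist <= d_max:
                    out.append(
                        HBond(
                            ligand_atom=lname,
                            protein_atom=pa.name,
                            protein_residue=f"{res.res_name}{res.seq_id}",
                            distance=dist,
                        )
                    )
    return out


def write_pose_pdb(pose: LigandPose, path: str | Path, seq_id: int = 1) -> None:
    """Write the pose as a HETATM block."""
    lines = []
    for k, a in enumerate(pose.atoms, start=1):
        name = a.name if len(a.name) == 4 else f" {a.name:<3s}"
        x, y, z = a.coord
        lines.append(
            f"HETATM{k:>5d} {name:<4s} {pose.ligand_name:>3s} L{seq_id:>4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          {a.element:>2s}"
        )
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def write_screen_table(rows: Sequence[tuple[str, ScreenResult]], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("target\tn_clashes\tn_contacts\tn_hbonds\tpassed\n")
        for target_id, res in rows:
            fh.write(
                f"{target_id}\t{res.n_clashes}\t{res.n_contacts}\t{len(res.hbonds)}\t"
                f"{int(res.passed)}\n"
            )
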