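"""Protein structure model, PDB I/O, sequence identity and redundancy removal.

The in-memory model is deliberately small: a :class:`Structure` is one parsed
PDB entry reduced to its first model, with polymer residues (each guaranteed a
Cα) and non-polymer HETATM groups ("ligands") kept separately.  A
:class:`StructureDB` is the searchable collection; redundancy is removed by
greedy longest-first clustering on global sequence identity, the same contract
as CD-HIT at a 0.95 identity cutoff.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np

logger = logging.getLogger(__name__)

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}
WATER_NAMES = {"HOH", "WAT", "DOD"}


class StructureError(ValueError):
    """Raised for unreadable or empty structure input."""


@dataclass
class Atom:
    name: str
    element: str
    coord: np.ndarray  # (3,) Å

    def __post_init__(self) -> None:
        self.coord = np.asarray(self.coord, dtype=float)
        if self.coord.shape != (3,) or not np.all(np.isfinite(self.coord)):
            raise ValueError(f"atom {self.name!r}: coord must be 3 finite components")
        if not self.name:
            raise ValueError("atom name must be non-empty")

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() in ("H", "D")


@dataclass
class Residue:
    chain_id: str
    seq_id: int
    res_name: str
    atoms: list[Atom]
    insertion_code: str = ""
    is_polymer: bool = True

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValueError("residue must have at least one atom")
        self.res_name = self.res_name.upper()

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def ca(self) -> Atom | None:
        return self.atom("CA")

    @property
    def one_letter(self) -> str:
        return THREE_TO_ONE.get(self.res_name, "X")

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if not a.is_hydrogen]

    def heavy_coords(self) -> np.ndarray:
        return np.array([a.coord for a in self.heavy_atoms()], dtype=float)


@dataclass
class Structure:
    struct_id: str
    residues: list[Residue] = field(default_factory=list)
    ligands: list[Residue] = field(default_factory=list)

    @property
    def sequence(self) -> str:
        return "".join(r.one_letter for r in self.residues)

    def ca_coords(self) -> np.ndarray:
        return np.array([r.ca.coord for r in self.residues], dtype=float)

    def heavy_coords(self) -> np.ndarray:
        """Protein (polymer) heavy-atom coordinates, ligands excluded."""
        chunks = [r.heavy_coords() for r in self.residues]
        return np.vstack(chunks) if chunks else np.empty((0, 3))


@dataclass
class StructureDB:
    structures: list[Structure]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [s.struct_id for s in self.structures]
        if len(set(ids)) != len(ids):
            raise ValueError("struct_ids must be unique within a database")

    def __len__(self) -> int:
        return len(self.structures)

    def __iter__(self):
        return iter(self.structures)

    def get(self, struct_id: str) -> Structure:
        for s in self.structures:
            if s.struct_id == struct_id:
                return s
        raise KeyError(struct_id)


# ---------------------------------------------------------------------------
# PDB I/O (reading through gemmi; minimal fixed-width writer for fixtures)
# ---------------------------------------------------------------------------

def parse_pdb(path: str | Path, keep_hetero: bool = True, struct_id: str | None = None) -> Structure:
    """Parse a PDB file into a :class:`Structure`.

    First model only; altloc other than blank/'A' discarded; waters excluded;
    HETATM groups become ligands when *keep_hetero*; hydrogens retained in the
    atom lists but flagged via :attr:`Atom.is_hydrogen`.  Polymer residues
    lacking a Cα are dropped with a logged warning.
    """
    path = Path(path)
    if not path.exists():
        raise StructureError(f"no such file: {path}")
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError) as exc:
        raise StructureError(f"cannot parse {path}: {exc}") from exc
    if len(st) == 0:
        raise StructureError(f"{path}: no models")
    st.remove_alternative_conformations()  # keeps blank/'A' conformer
    model = st[0]

    residues: list[Residue] = []
    ligands: list[Residue] = []
    for chain in model:
        for res in chain:
            if res.name in WATER_NAMES:
                continue
            atoms = [
                Atom(name=a.name, element=a.element.name, coord=np.array(a.pos.tolist()))
                for a in res
            ]
            if not atoms:
                continue
            is_polymer = res.het_flag != "H"
            r = Residue(
                chain_id=chain.name,
                seq_id=res.seqid.num,
                insertion_code=(res.seqid.icode or "").strip(),
                res_name=res.name,
                atoms=atoms,
                is_polymer=is_polymer,
            )
            if is_polymer:
                if r.ca is None:
                    logger.warning(
                        "%s: dropping residue %s %s%d without CA",
                        path.name, res.name, chain.name, res.seqid.num,
                    )
                    continue
                residues.append(r)
            elif keep_hetero:
                r.is_polymer = False
                ligands.append(r)

    if not residues:
        raise StructureError(f"{path}: no polymer residues")
    return Structure(struct_id=struct_id or path.stem, residues=residues, ligands=ligands)


def write_pdb(structure: Structure, path: str | Path) -> None:
    """Write a Structure as minimal PDB text (ATOM/HETATM/TER/END)."""
    lines: list[str] = []
    serial = 1

    def fmt(record: str, res: Residue, atom: Atom, serial: int) -> str:
        name = atom.name if len(atom.name) == 4 else f" {atom.name:<3s}"
        x, y, z = atom.coord
        return (
            f"{record:<6s}{serial:>5d} {name:<4s} {res.res_name:>3s} "
            f"{res.chain_id[:1]:1s}{res.seq_id:>4d}{(res.insertion_code or ' '):1s}   "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
            f"{atom.element:>2s}"
        )

    for res in structure.residues:
        for atom in res.atoms:
            lines.append(fmt("ATOM", res, atom, serial))
            serial += 1
    lines.append(f"TER   {serial:>5d}")
    serial += 1
    for res in structure.ligands:
        for atom in res.atoms:
            lines.append(fmt("HETATM", res, atom, serial))
            serial += 1
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def write_manifest(db: StructureDB, path: str | Path) -> None:
    """Database manifest TSV: struct_id, n_residues, n_ligands, sequence."""
    with open(path, "w") as fh:
        fh.write("struct_id\tn_residues\tn_ligands\tsequence\n")
        for s in db:
            fh.write(f"{s.struct_id}\t{len(s.residues)}\t{len(s.ligands)}\t{s.sequence}\n")


# ---------------------------------------------------------------------------
# Sequence identity and greedy redundancy removal
# ---------------------------------------------------------------------------

_GAP = -1
_MATCH = 1
_MISMATCH = 0


def _nw_score_matrix(a: str, b: str) -> np.ndarray:
    """Global alignment DP matrix (match +1, mismatch 0, linear gap −1).

    Row recurrence is vectorised: with a linear gap the left-dependency
    H[i,j] = max(T[j], H[i,j-1] − 1) collapses to a running maximum of
    T[k] + k, so each row costs O(m) numpy work.
    """
    n, m = len(a), len(b)
    bb = np.frombuffer(b.encode("ascii"), dtype=np.uint8)
    H = np.empty((n + 1, m + 1), dtype=np.int32)
    H[0, :] = _GAP * np.arange(m + 1)
    ar = np.frombuffer(a.encode("ascii"), dtype=np.uint8)
    j_idx = np.arange(1, m + 1)
    for i in range(1, n + 1):
        s = np.where(bb == ar[i - 1], _MATCH, _MISMATCH)
        T = np.maximum(H[i - 1, :-1] + s, H[i - 1, 1:] + _GAP)
        # prepend the fixed first column, then running max of T[k]+k minus j
        first = i * _GAP
        cand = np.maximum.accumulate(np.concatenate(([first + 0], T + j_idx)))
        H[i, 0] = first
        H[i, 1:] = cand[1:] - j_idx
    return H


def _nw_traceback(a: str, b: str, H: np.ndarray) -> list[tuple[int, int]]:
    """Aligned index pairs; ties resolved diagonal > up > left (deterministic)."""
    pairs: list[tuple[int, int]] = []
    i, j = len(a), len(b)
    while i > 0 and j > 0:
        s = _MATCH if a[i - 1] == b[j - 1] else _MISMATCH
        if H[i, j] == H[i - 1, j - 1] + s:
            pairs.append((i - 1, j - 1))
            i -= 1
            j -= 1
        elif H[i, j] == H[i - 1, j] + _GAP:
            i -= 1
        else:
            j -= 1
    pairs.reverse()
    return pairs


def sequence_identity(seq_a: str, seq_b: str) -> float:
    """Global-alignment identity, normalised by the shorter sequence length.

    Needleman–Wunsch with match +1, mismatch 0, gap −1; identity is the count
    of identical aligned positions divided by min(len(a), len(b)) — the CD-HIT
    denominator convention.
    """
    if not seq_a or not seq_b:
        raise ValueError("sequences must be non-empty")
    H = _nw_score_matrix(seq_a, seq_b)
    pairs = _nw_traceback(seq_a, seq_b, H)
    ident = sum(1 for i, j in pairs if seq_a[i] == seq_b[j])
    return ident / min(len(seq_a), len(seq_b))


def cluster_representatives(db: StructureDB, cutoff: float) -> StructureDB:
    """Greedy longest-first identity clustering; returns representatives only.

    Structures are visited in order of descending sequence length (stable in
    the original order on ties); each joins the first representative with
    identity ≥ *cutoff*, else founds a new cluster.  Representative order is
    founding order.
    """
    if not 0 < cutoff <= 1:
        raise ValueError("cutoff must be in (0, 1]")
    order = sorted(range(len(db.structures)), key=lambda k: (-len(db.structures[k].sequence), k))
    reps: list[Structure] = []
    for k in order:
        s = db.structures[k]
        for rep in reps:
            if sequence_identity(s.sequence, rep.sequence) >= cutoff:
                break
        else:
            reps.append(s)
    meta = dict(db.meta)
    meta["clustered_at"] = cutoff
    return StructureDB(structures=reps, meta=meta)


def load_structure_dir(directory: str | Path, keep_hetero: bool = True) -> StructureDB:
    """Parse every ``*.pdb`` file under *directory* into a database."""
    directory = Path(directory)
    structures = [
        parse_pdb(p, keep_hetero=keep_hetero) for p in sorted(directory.glob("*.pdb"))
    ]
    if not structures:
        raise StructureError(f"no PDB files under {directory}")
    return StructureDB(structures=structures, meta={"source": str(directory)})
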