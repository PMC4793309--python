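"""Synthetic structures with known ground truth for benchmarking the search.

Decoys are self-avoiding Cα random walks carrying Cβ and backbone N/O stub
atoms; a benchmark database mixes clean decoys with decoys into which a noisy,
substitution-perturbed copy of a query binding site has been planted at the
surface.  A fixed-topology 13-heavy-atom ligand (planar ring, four oxygens)
stands in for acetylsalicylic acid.  Every generator is a pure function of its
seed; fixtures are written as ordinary PDB files so all other modules consume
them through the normal reader.

These models are deliberately minimal: geometry is realistic at the level the
search engine and the pose gate observe (representative-atom distances, heavy
atom packing), not at the level of real protein stereochemistry.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .sites import BindingSite, extract_site
from .search import substitution_sets
from .structures import Atom, ONE_TO_THREE, Residue, Structure, StructureDB

logger = logging.getLogger(__name__)

AA20 = "ACDEFGHIKLMNPQRSTVWY"

CA_STEP = 3.8          # consecutive Cα spacing, Å
MIN_NONADJ = 4.0       # minimum non-adjacent Cα–Cα distance, Å

# sampling weights loosely following binding-pocket composition (hydrophobics
# and glycine enriched, with charged/polar residues represented)
POCKET_WEIGHTS = {
    "L": 9, "V": 7, "I": 6, "A": 6, "F": 5, "G": 6, "Y": 5, "C": 4,
    "S": 4, "T": 4, "K": 4, "D": 4, "H": 3, "N": 3, "E": 3, "Q": 2,
    "R": 2, "M": 2, "W": 2, "P": 2,
}


class GenerationError(RuntimeError):
    pass


@dataclass(frozen=True)
class PlantSpec:
    noise_sigma: float = 0.3    # Å, per-coordinate Gaussian
    n_substitutions: int = 1    # BLOSUM62-compatible residue swaps
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")


@dataclass
class BenchmarkTruth:
    planted_ids: set[str]
    db_size: int
    spec: PlantSpec
    mappings: dict[str, dict[int, int]] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "planted_ids": sorted(self.planted_ids),
            "db_size": self.db_size,
            "spec": {
                "noise_sigma": self.spec.noise_sigma,
                "n_substitutions": self.spec.n_substitutions,
                "seed": self.spec.seed,
            },
            "mappings": {k: {str(q): t for q, t in v.items()} for k, v in self.mappings.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise ValueError("zero vector")
    return v / n


def _perp(v: np.ndarray) -> np.ndarray:
    ref = np.array([0.0, 0.0, 1.0]) if abs(v[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    return _unit(np.cross(v, ref))


def _rotation_between(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Proper rotation sending unit vector u onto unit vector v (Rodrigues)."""
    c = float(np.dot(u, v))
    if c > 1 - 1e-12:
        return np.eye(3)
    if c < -1 + 1e-12:
        p = _perp(u)
        return _axis_rotation(p, np.pi)
    axis = _unit(np.cross(u, v))
    return _axis_rotation(axis, float(np.arccos(np.clip(c, -1, 1))))


def _axis_rotation(axis: np.ndarray, angle: float) -> np.ndarray:
    ka = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + np.sin(angle) * ka + (1 - np.cos(angle)) * (ka @ ka)


def _stub_atoms(ca: np.ndarray, i: int, n: int, all_ca: np.ndarray) -> list[Atom]:
    """CA plus deterministic CB/N/O stubs from the local chain frame."""
    if i > 0:
        u_prev = _unit(all_ca[i] - all_ca[i - 1])
    else:
        u_prev = _unit(all_ca[i] - all_ca[i + 1]) * -1 if n > 1 else np.array([1.0, 0, 0])
    if i < n - 1:
        u_next = _unit(all_ca[i + 1] - all_ca[i])
    else:
        u_next = u_prev
    tangent = u_prev + u_next
    e1 = _unit(tangent) if np.linalg.norm(tangent) > 1e-6 else u_prev
    e2 = _perp(e1)
    e3 = np.cross(e1, e2)
    return [
        Atom(name="N", element="N", coord=ca - 1.25 * e1 + 0.35 * e3),
        Atom(name="CA", element="C", coord=ca),
        Atom(name="CB", element="C", coord=ca + 1.5 * e2),
        Atom(name="O", element="O", coord=ca + 1.05 * e1 + 0.65 * e3),
    ]


def _build_chain(ca_coords: np.ndarray, names3: list[str], chain_id: str = "A",
                 first_seq_id: int = 1) -> list[Residue]:
    n = len(names3)
    residues = []
    for i in range(n):
        residues.append(
            Residue(
                chain_id=chain_id,
                seq_id=first_seq_id + i,
                res_name=names3[i],
                atoms=_stub_atoms(ca_coords[i], i, n, ca_coords),
            )
        )
    return residues


def _as_rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def _random_direction(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return _unit(v)


def _self_avoiding_walk(
    n_res: int,
    rng: np.random.Generator,
    start: np.ndarray | None = None,
    exclude: np.ndarray | None = None,
    exclusion_radius: float = 0.0,
    step_retries: int = 200,
    restarts: int = 50,
) -> np.ndarray:
    """Cα walk with 3.8 Å steps, ≥4.0 Å non-adjacent separation.

    Optionally keeps every position at least *exclusion_radius* from each row
    of *exclude* (used to keep decoy tails away from a planted pocket region).
    """
    for _ in range(restarts):
        pos = [np.zeros(3) if start is None else np.asarray(start, dtype=float)]
        ok = True
        for _i in range(1, n_res):
            placed = False
            for _r in range(step_retries):
                cand = pos[-1] + CA_STEP * _random_direction(rng)
                prior = np.array(pos[:-1]) if len(pos) > 1 else None
                if prior is not None and np.linalg.norm(prior - cand, axis=1).min() < MIN_NONADJ:
                    continue
                if exclude is not None and exclusion_radius > 0:
                    if np.linalg.norm(exclude - cand, axis=1).min() < exclusion_radius:
                        continue
                pos.append(cand)
                placed = True
                break
            if not placed:
                ok = False
                break
        if ok:
            return np.array(pos)
    raise GenerationError(f"self-avoiding walk failed after {restarts} restarts")


def make_decoy(n_res: int, seed) -> Structure:
    """Random single-chain decoy: self-avoiding Cα walk with stub atoms."""
    if n_res < 10:
        raise ValueError("n_res must be at least 10")
    rng = _as_rng(seed)
    ca = _self_avoiding_walk(n_res, rng)
    names = [ONE_TO_THREE[AA20[k]] for k in rng.integers(0, 20, size=n_res)]
    sid = f"DEC{(seed if isinstance(seed, int) else 0):08d}" if isinstance(seed, int) else "DEC"
    return Structure(struct_id=sid, residues=_build_chain(ca, names))


def make_toy_ligand(seed=0) -> Residue:
    """Aspirin-like rigid ligand: 13 heavy atoms, planar 6-ring, 4 oxygens.

    Geometry is fixed and deterministic (the seed is accepted for interface
    uniformity but does not perturb the coordinates).
    """
    ring = [
        1.39 * np.array([np.cos(k * np.pi / 3), np.sin(k * np.pi / 3), 0.0])
        for k in range(6)
    ]
    c1, c2 = ring[0], ring[1]
    c7 = c1 + 1.50 * _unit(c1)
    o1 = c7 + 1.23 * _unit(np.array([0.60, 1.07, 0.0]))
    o2 = c7 + 1.31 * _unit(np.array([0.60, -1.07, 0.0]))
    o3 = c2 + 1.43 * _unit(c2)
    d8 = _unit(np.array([0.50, 0.87, 0.80]))
    c8 = o3 + 1.36 * d8
    o4 = c8 + 1.23 * _unit(np.array([1.0, 0.0, 0.6]))
    c9 = c8 + 1.50 * _unit(np.array([-0.3, 0.5, 1.0]))
    coords = ring + [c7, o1, o2, o3, c8, o4, c9]
    names = ["C1", "C2", "C3", "C4", "C5", "C6", "C7", "O1", "O2", "O3", "C8", "O4", "C9"]
    elements = [n[0] for n in names]
    atoms = [Atom(name=n, element=e, coord=c) for n, e, c in zip(names, elements, coords)]
    return Residue(chain_id="L", seq_id=1, res_name="ASL", atoms=atoms, is_polymer=False)


# bonded pairs of the toy ligand (atom-name pairs), for geometry checks
TOY_LIGAND_BONDS = [
    ("C1", "C2"), ("C2", "C3"), ("C3", "C4"), ("C4", "C5"), ("C5", "C6"),
    ("C6", "C1"), ("C1", "C7"), ("C7", "O1"), ("C7", "O2"), ("C2", "O3"),
    ("O3", "C8"), ("C8", "O4"), ("C8", "C9"),
]


def _fibonacci_sphere(n: int) -> np.ndarray:
    k = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * k / n)
    theta = np.pi * (1 + 5**0.5) * k
    return np.stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)], axis=1
    )


def make_query_complex(
    seed,
    n_pocket: int = 20,
    n_tail: int = 30,
    ca_radius: float = 8.2,
    struct_id: str | None = None,
) -> Structure:
    """Synthetic query complex: a pocket shell around the toy ligand plus a tail.

    Pocket Cα sit on a jittered sphere of *ca_radius* around the ligand with
    Cβ pointing inward; a self-avoiding tail is grown outside the pocket
    region.  Residue types are drawn from a pocket-like composition.  The
    ligand is stored as a non-polymer group, so ``extract_site`` on the result
    yields a site inside the realistic 10–26 residue envelope.
    """
    rng = _as_rng(seed)
    ligand = make_toy_ligand()
    lig_xyz = ligand.heavy_coords()
    center = lig_xyz.mean(axis=0)
    for a in ligand.atoms:
        a.coord = a.coord - center

    directions = _fibonacci_sphere(n_pocket)
    ca = directions * ca_radius + rng.normal(scale=0.3, size=(n_pocket, 3))
    letters = list(POCKET_WEIGHTS)
    w = np.array([POCKET_WEIGHTS[c] for c in letters], dtype=float)
    w /= w.sum()
    names = [ONE_TO_THREE[letters[k]] for k in rng.choice(len(letters), size=n_pocket, p=w)]

    residues: list[Residue] = []
    for i in range(n_pocket):
        inward = -_unit(ca[i])
        e1 = _perp(inward)
        e3 = np.cross(inward, e1)
        atoms = [
            Atom(name="N", element="N", coord=ca[i] + 1.0 * inward + 0.7 * e1),
            Atom(name="CA", element="C", coord=ca[i]),
            Atom(name="CB", element="C", coord=ca[i] + 1.5 * inward),
            Atom(name="O", element="O", coord=ca[i] + 1.1 * inward - 0.6 * e1),
        ]
        residues.append(
            Residue(chain_id="A", seq_id=i + 1, res_name=names[i], atoms=atoms)
        )

    start = ca[0] + 7.0 * _unit(ca[0])
    tail_ca = _self_avoiding_walk(
        n_tail, rng, start=start, exclude=np.vstack([ca, np.zeros((1, 3))]),
        exclusion_radius=6.5,
    )
    tail_names = [ONE_TO_THREE[AA20[k]] for k in rng.integers(0, 20, size=n_tail)]
    residues.extend(
        _build_chain(tail_ca, tail_names, first_seq_id=n_pocket + 1)
    )
    return Structure(
        struct_id=struct_id or "QUERY", residues=residues, ligands=[ligand]
    )


def plant_site(
    decoy: Structure,
    site: BindingSite,
    spec: PlantSpec,
    pocket_direction: np.ndarray | None = None,
    ligand_coords: np.ndarray | None = None,
    cavity_clearance: float = 3.2,
) -> tuple[Structure, dict[int, int]]:
    """Replace a surface residue cluster of *decoy* with a noisy copy of *site*.

    The cluster is the site-size set of residues nearest to the decoy residue
    farthest from the centroid (a surface patch).  Site representative
    coordinates get per-coordinate Gaussian noise (σ = ``spec.noise_sigma``),
    a rigid re-pose into the decoy frame oriented so the pocket opening
    (*pocket_direction*, query frame) faces outward, and
    ``spec.n_substitutions`` random BLOSUM62-compatible residue swaps.
    When *ligand_coords* (query-frame ligand heavy atoms) are given, the
    cavity is kept open: unplanted residues whose Cα would fall within
    *cavity_clearance* of the re-posed ligand position are pushed out of it,
    emulating that a planted pocket is an actual pocket.
    Returns the modified structure and the true mapping
    {query residue index -> decoy residue index}.
    """
    n = site.size
    if n > len(decoy.residues):
        raise GenerationError("decoy smaller than the site to plant")
    if spec.n_substitutions > n:
        raise ValueError("more substitutions than site residues")
    rng = np.random.default_rng(spec.seed)
    ca = decoy.ca_coords()
    centroid = ca.mean(axis=0)

    seed_idx = int(np.argmax(np.linalg.norm(ca - centroid, axis=1)))
    order = np.argsort(np.linalg.norm(ca - ca[seed_idx], axis=1))
    cluster = sorted(int(k) for k in order[:n])
    cluster_centroid = ca[cluster].mean(axis=0)
    u_out = _unit(cluster_centroid - centroid)

    S = site.rep_coords
    cS = S.mean(axis=0)
    if pocket_direction is None:
        # pocket opening approximated by the least-populated principal axis
        _, _, vt = np.linalg.svd(S - cS)
        u_q = vt[2]
    else:
        u_q = _unit(np.asarray(pocket_direction, dtype=float))
    R = _axis_rotation(u_out, float(rng.uniform(0, 2 * np.pi))) @ _rotation_between(u_q, u_out)

    noise = rng.normal(scale=spec.noise_sigma, size=S.shape) if spec.noise_sigma > 0 else 0.0
    planted_ca = (S - cS + noise) @ R.T + cluster_centroid

    # residue codes with k substitutions drawn from the site's substitution sets
    codes = list(site.codes)
    subs = substitution_sets(site, 1)
    # only positions with a non-trivial substitution set can be swapped
    # (e.g. cysteine has no BLOSUM62 neighbour scoring >= 1 besides itself)
    eligible = [p for p in range(n) if subs.allowed[p] - {codes[p]}]
    k_swaps = min(spec.n_substitutions, len(eligible))
    if k_swaps < spec.n_substitutions:
        logger.warning(
            "only %d/%d site positions are substitutable", k_swaps, spec.n_substitutions
        )
    swap_positions = rng.choice(len(eligible), size=k_swaps, replace=False)
    for pi in swap_positions:
        p = eligible[int(pi)]
        options = sorted(subs.allowed[p] - {codes[p]})
        codes[p] = options[rng.integers(len(options))]

    new_ca = ca.copy()
    names = [r.res_name for r in decoy.residues]
    mapping: dict[int, int] = {}
    for qi, di in enumerate(cluster):
        new_ca[di] = planted_ca[qi]
        names[di] = ONE_TO_THREE.get(codes[qi], "ALA")
        mapping[qi] = di
    if ligand_coords is not None:
        lig = (np.asarray(ligand_coords, dtype=float) - cS) @ R.T + cluster_centroid
        lig_c = lig.mean(axis=0)
        in_cluster = set(cluster)
        for di in range(len(new_ca)):
            if di in in_cluster:
                continue
            d = np.linalg.norm(lig - new_ca[di], axis=1).min()
            # stub atoms reach ~1.6 Å from Cα, so clear Cα to clearance + 1.6
            needed = cavity_clearance + 1.6
            if d < needed:
                away = new_ca[di] - lig_c
                away = _unit(away) if np.linalg.norm(away) > 1e-9 else u_out * -1
                new_ca[di] = new_ca[di] + (needed - d + 0.2) * away
    residues = _build_chain(new_ca, names)
    # planted residues get pocket-style stubs (side chain toward the pocket
    # centre), matching how pocket residues sit around a bound ligand
    pocket_centre = (
        lig.mean(axis=0) if ligand_coords is not None else planted_ca.mean(axis=0)
    )
    for qi, di in mapping.items():
        ca_i = new_ca[di]
        inward = pocket_centre - ca_i
        inward = _unit(inward) if np.linalg.norm(inward) > 1e-9 else u_out * -1
        e1 = _perp(inward)
        residues[di].atoms = [
            Atom(name="N", element="N", coord=ca_i + 1.0 * inward + 0.7 * e1),
            Atom(name="CA", element="C", coord=ca_i),
            Atom(name="CB", element="C", coord=ca_i + 1.5 * inward),
            Atom(name="O", element="O", coord=ca_i + 1.1 * inward - 0.6 * e1),
        ]
    # keep original chain/seq numbering
    for new, old in zip(residues, decoy.residues):
        new.chain_id = old.chain_id
        new.seq_id = old.seq_id
    return Structure(struct_id=decoy.struct_id, residues=residues), mapping


def make_benchmark(
    site: BindingSite,
    n_planted: int = 10,
    n_decoys: int = 100,
    spec: PlantSpec = PlantSpec(),
    decoy_n_res: int = 80,
    pocket_direction: np.ndarray | None = None,
    ligand_coords: np.ndarray | None = None,
) -> tuple[StructureDB, BenchmarkTruth]:
    """Seeded database of planted-pocket structures mixed with clean decoys."""
    if n_planted < 1 or n_decoys < 1:
        raise ValueError("counts must be at least 1")
    rng = np.random.default_rng(spec.seed)
    seeds = rng.integers(0, 2**31 - 1, size=2 * (n_planted + n_decoys))

    entries: list[tuple[Structure, dict[int, int] | None]] = []
    for i in range(n_planted):
        decoy = make_decoy(decoy_n_res, int(seeds[2 * i]))
        plant = PlantSpec(
            noise_sigma=spec.noise_sigma,
            n_substitutions=spec.n_substitutions,
            seed=int(seeds[2 * i + 1]),
        )
        planted, mapping = plant_site(
            decoy, site, plant, pocket_direction, ligand_coords=ligand_coords
        )
        entries.append((planted, mapping))
    off = 2 * n_planted
    for j in range(n_decoys):
        entries.append((make_decoy(decoy_n_res, int(seeds[off + 2 * j])), None))

    perm = rng.permutation(len(entries))
    structures = []
    truth = BenchmarkTruth(planted_ids=set(), db_size=len(entries), spec=spec)
    for rank, k in enumerate(perm):
        s, mapping = entries[k]
        s = Structure(struct_id=f"SYN{rank:04d}", residues=s.residues, ligands=s.ligands)
        structures.append(s)
        if mapping is not None:
            truth.planted_ids.add(s.struct_id)
            truth.mappings[s.struct_id] = mapping
    return StructureDB(structures=structures, meta={"benchmark": True}), truth


def make_decoy_db(n: int, seed, n_res: int = 80) -> StructureDB:
    """Independent decoy-only database (e.g. for null calibration)."""
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2**31 - 1, size=n)
    structures = []
    for i in range(n):
        s = make_decoy(n_res, int(seeds[i]))
        structures.append(Structure(struct_id=f"NUL{i:04d}", residues=s.residues))
    return StructureDB(structures=structures, meta={"decoys": True})
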