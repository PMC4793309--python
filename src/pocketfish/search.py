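"""Contact-matrix local structural alignment: site search against a database.

Given a query binding site (ordered residues with representative-atom
coordinates), the engine looks for residue combinations in each database
structure whose residue types are BLOSUM62-compatible with the query and whose
inter-residue distance pattern matches the query's contact matrix.  Candidate
combinations are generated by an anchor-pair / incremental-extension search
with distance pruning, filtered by contact-matrix average deviation (CMAD),
superposed onto the query by the Kabsch algorithm, and ranked by an empirical
RMSD P-value calibrated on random residue combinations from decoy structures.
E-value = P-value × database size; hits with E < 0.01 are significant.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from Bio.Align import substitution_matrices
from scipy.spatial.distance import pdist, squareform

from .sites import BindingSite, ContactMatrix, contact_matrix
from .structures import Residue, Structure, StructureDB

logger = logging.getLogger(__name__)

AA20 = "ACDEFGHIKLMNPQRSTVWY"
_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def blosum62(a: str, b: str) -> float:
    return float(_BLOSUM62[a, b])


# ---------------------------------------------------------------------------
# Substitution sets
# ---------------------------------------------------------------------------

@dataclass
class SubstitutionSet:
    """Allowed one-letter codes per query residue position."""
    codes: str                      # query residue codes, length n
    allowed: list[frozenset[str]]   # per position

    def __post_init__(self) -> None:
        if len(self.codes) != len(self.allowed):
            raise ValueError("one allowed-set per query residue")
        for q, s in zip(self.codes, self.allowed):
            if q in AA20 and q not in s:
                raise ValueError(f"own code {q} missing from its substitution set")


def substitution_sets(site: BindingSite, score_cutoff: int = 1) -> SubstitutionSet:
    """Per-residue sets {t : BLOSUM62(q, t) ≥ score_cutoff}.

    A residue's own code is always retained, even under a cutoff that would
    exclude it; non-standard codes map to X and admit all 20 codes (warned).
    """
    allowed: list[frozenset[str]] = []
    for q in site.codes:
        if q not in AA20:
            logger.warning("site %s: non-standard residue code %r -> all codes", site.site_id, q)
            allowed.append(frozenset(AA20))
            continue
        s = {t for t in AA20 if blosum62(q, t) >= score_cutoff}
        s.add(q)
        allowed.append(frozenset(s))
    return SubstitutionSet(codes=site.codes, allowed=allowed)


# ---------------------------------------------------------------------------
# CMAD and Kabsch
# ---------------------------------------------------------------------------

def cmad(query_cm: ContactMatrix, cand_coords: np.ndarray) -> float:
    """Contact-matrix average deviation: mean over i<j of |d_q(i,j) − d_c(i,j)|."""
    cand_coords = np.asarray(cand_coords, dtype=float)
    n = query_cm.dist.shape[0]
    if cand_coords.shape != (n, 3):
        raise ValueError(f"candidate has {cand_coords.shape} coords, query site has {n} residues")
    if n < 3:
        raise ValueError("need at least 3 residues")
    dq = squareform(query_cm.dist, checks=False)
    dc = pdist(cand_coords)
    return float(np.mean(np.abs(dq - dc)))


@dataclass
class RigidTransform:
    rotation: np.ndarray    # (3, 3) proper rotation
    translation: np.ndarray  # (3,)

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        if not np.allclose(self.rotation @ self.rotation.T, np.eye(3), atol=1e-8):
            raise ValueError("rotation is not orthogonal")
        if not np.isclose(np.linalg.det(self.rotation), 1.0, atol=1e-8):
            raise ValueError("rotation must be proper (det = +1)")

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, dtype=float) @ self.rotation.T + self.translation

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(rotation=np.eye(3), translation=np.zeros(3))


def kabsch(coords_a: np.ndarray, coords_b: np.ndarray) -> tuple[RigidTransform, float]:
    """Least-squares rigid superposition of *a* onto *b* (rows correspond).

    Returns the proper-rotation transform minimising RMSD and the RMSD itself.
    Reflections are excluded by flipping the sign of the smallest singular
    direction when the raw solution is improper.
    """
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3 or a.shape[0] < 3:
        raise ValueError("need matching (n>=3, 3) coordinate arrays")
    ca, cb = a.mean(axis=0), b.mean(axis=0)
    A, B = a - ca, b - cb
    H = A.T @ B
    if np.allclose(H, 0.0, atol=1e-12):
        raise ValueError("degenerate (rank-0) point sets")
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cb - R @ ca
    diff = A @ R.T - B
    rmsd = float(np.sqrt((diff ** 2).sum() / a.shape[0]))
    return RigidTransform(rotation=R, translation=t), rmsd


# ---------------------------------------------------------------------------
# Candidate enumeration (anchor pair + incremental extension)
# ---------------------------------------------------------------------------

@dataclass
class CandidateSet:
    mappings: list[tuple[int, ...]]  # target residue indices, in query order
    truncated: bool = False


def _target_tables(target: Structure) -> tuple[str, np.ndarray]:
    codes = "".join(r.one_letter for r in target.residues)
    coords = target.ca_coords()
    return codes, coords


def enumerate_candidates(
    site: BindingSite,
    target: Structure,
    subs: SubstitutionSet,
    pair_tol: float = 2.0,
    max_candidates: int = 50_000,
    rep_atom: str = "CA",
) -> CandidateSet:
    """All code-compatible residue combinations whose pairwise distances match.

    Anchor-and-extend: the query residue pair with the largest (most
    discriminating) separation anchors the search; target residue pairs with
    compatible codes and |Δd| ≤ *pair_tol* seed partial mappings, extended one
    query residue at a time with every already-assigned pair checked against
    the same tolerance.  Emission is capped at *max_candidates* (truncation is
    flagged, not an error) and the returned mappings are sorted
    lexicographically by target residue indices.
    """
    if pair_tol <= 0:
        raise ValueError("pair_tol must be positive")
    n = site.size
    codes, coords = _target_tables(target)
    if rep_atom == "CB":
        coords = np.array(
            [
                (target.residues[i].atom("CB") or target.residues[i].ca).coord
                for i in range(len(target.residues))
            ]
        )
    dq = squareform(pdist(site.rep_coords))
    compat = [
        np.array([k for k, c in enumerate(codes) if c in subs.allowed[i]], dtype=int)
        for i in range(n)
    ]
    if any(len(c) == 0 for c in compat):
        return CandidateSet(mappings=[], truncated=False)
    dt = squareform(pdist(coords))

    # anchor: widest query pair, ties by lowest (i, j)
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    ai, aj = max(pairs, key=lambda p: (dq[p[0], p[1]], -p[0], -p[1]))
    rest = sorted((k for k in range(n) if k not in (ai, aj)), key=lambda k: (len(compat[k]), k))
    order = [ai, aj] + rest

    mappings: list[tuple[int, ...]] = []
    truncated = False
    assignment: dict[int, int] = {}

    def extend(depth: int) -> bool:
        """DFS; returns False when the cap is hit."""
        nonlocal truncated
        if depth == n:
            mappings.append(tuple(assignment[q] for q in range(n)))
            if len(mappings) >= max_candidates:
                truncated = True
                return False
            return True
        q = order[depth]
        for t in compat[q]:
            if t in assignment.values():
                continue
            ok = True
            for q2, t2 in assignment.items():
                if abs(dt[t, t2] - dq[q, q2]) > pair_tol:
                    ok = False
                    break
            if not ok:
                continue
            assignment[q] = t
            alive = extend(depth + 1)
            del assignment[q]
            if not alive:
                return False
        return True

    extend(0)
    if truncated:
        logger.info(
            "%s vs %s: candidate cap %d reached", site.site_id, target.struct_id, max_candidates
        )
    mappings.sort()
    return CandidateSet(mappings=mappings, truncated=truncated)


# ---------------------------------------------------------------------------
# Empirical null, P-value, E-value
# ---------------------------------------------------------------------------

@dataclass
class NullModel:
    n_samples: int
    rmsd_samples: np.ndarray  # sorted ascending
    seed: int
    site_size: int

    def __post_init__(self) -> None:
        self.rmsd_samples = np.asarray(self.rmsd_samples, dtype=float)
        if self.n_samples < 100:
            raise ValueError("need at least 100 null samples")
        if np.any(np.diff(self.rmsd_samples) < 0):
            raise ValueError("null samples must be sorted ascending")


def calibrate_null(
    site: BindingSite,
    decoy_db: StructureDB,
    n_samples: int = 1000,
    seed: int = 0,
    score_cutoff: int = 1,
    max_attempts_factor: int = 50,
) -> NullModel:
    """Empirical RMSD null from random code-compatible residue combinations.

    Each sample draws a decoy structure uniformly, then an injective random
    assignment of code-compatible residues (one per query position), and
    records its Kabsch RMSD to the query site.  If fewer than *n_samples*
    feasible tuples are found within the attempt budget, all found samples are
    used with a warning.
    """
    if len(decoy_db) == 0:
        raise ValueError("decoy database is empty")
    subs = substitution_sets(site, score_cutoff)
    rng = np.random.default_rng(seed)
    n = site.size

    per_struct: list[tuple[np.ndarray, list[np.ndarray]]] = []
    for s in decoy_db:
        codes, coords = _target_tables(s)
        compat = [
            np.array([k for k, c in enumerate(codes) if c in subs.allowed[i]], dtype=int)
            for i in range(n)
        ]
        if all(len(c) > 0 for c in compat):
            per_struct.append((coords, compat))
    if not per_struct:
        raise ValueError("no decoy structure is code-compatible with the site")

    samples: list[float] = []
    attempts = 0
    budget = max_attempts_factor * n_samples
    while len(samples) < n_samples and attempts < budget:
        attempts += 1
        coords, compat = per_struct[rng.integers(len(per_struct))]
        used: set[int] = set()
        picks: list[int] = []
        feasible = True
        for i in range(n):
            options = [t for t in compat[i] if t not in used]
            if not options:
                feasible = False
                break
            t = options[rng.integers(len(options))]
            used.add(t)
            picks.append(t)
        if not feasible:
            continue
        _, r = kabsch(site.rep_coords, coords[np.array(picks)])
        samples.append(r)
    if len(samples) < n_samples:
        logger.warning("null calibration: only %d/%d feasible tuples", len(samples), n_samples)
    return NullModel(
        n_samples=len(samples),
        rmsd_samples=np.sort(np.array(samples)),
        seed=seed,
        site_size=n,
    )


def p_value(null: NullModel, rmsd: float) -> float:
    """Add-one empirical P-value: (1 + #{null ≤ rmsd}) / (n_samples + 1)."""
    k = int(np.searchsorted(null.rmsd_samples, rmsd, side="right"))
    return (1 + k) / (null.n_samples + 1)


def e_value(p: float, db_size: int) -> float:
    return p * db_size


# ---------------------------------------------------------------------------
# Search
# ---------------------------------------------------------------------------

@dataclass
class SearchConfig:
    score_cutoff: int = 1
    pair_tol: float = 2.0
    cmad_cutoff: float = 1.5
    max_candidates: int = 50_000
    e_cutoff: float = 0.01
    rep_atom: str = "CA"


@dataclass
class SiteMatch:
    query_site_id: str
    target_struct: str
    mapping: list[tuple[int, Residue]]  # query residue index -> target residue
    target_indices: tuple[int, ...]
    cmad: float
    rmsd: float
    transform: RigidTransform
    p_value: float = 1.0
    e_value: float = float("inf")

    def __post_init__(self) -> None:
        idx = [t for _, t in self.mapping]
        if len({id(r) for r in idx}) != len(idx):
            raise ValueError("mapping must be injective")
        if self.cmad < 0 or self.rmsd < 0:
            raise ValueError("cmad and rmsd must be non-negative")


def best_match(
    site: BindingSite,
    target: Structure,
    subs: SubstitutionSet,
    config: SearchConfig,
    query_cm: ContactMatrix | None = None,
) -> SiteMatch | None:
    """Best (lowest-RMSD) CMAD-passing match of the site in one structure."""
    query_cm = query_cm or contact_matrix(site)
    cands = enumerate_candidates(
        site, target, subs,
        pair_tol=config.pair_tol,
        max_candidates=config.max_candidates,
        rep_atom=config.rep_atom,
    )
    if not cands.mappings:
        return None
    _, coords = _target_tables(target)
    if config.rep_atom == "CB":
        coords = np.array([(r.atom("CB") or r.ca).coord for r in target.residues])
    dq = squareform(pdist(site.rep_coords))

    best: SiteMatch | None = None
    for mapping in cands.mappings:
        cand = coords[np.array(mapping)]
        dev = float(np.mean(np.abs(squareform(dq, checks=False) - pdist(cand))))
        if dev >= config.cmad_cutoff:
            continue
        tr, r = kabsch(site.rep_coords, cand)
        if best is None or (r, dev) < (best.rmsd, best.cmad):
            best = SiteMatch(
                query_site_id=site.site_id,
                target_struct=target.struct_id,
                mapping=[(qi, target.residues[ti]) for qi, ti in enumerate(mapping)],
                target_indices=mapping,
                cmad=dev,
                rmsd=r,
                transform=tr,
            )
    return best


def search(
    site: BindingSite,
    db: StructureDB,
    null: NullModel,
    config: SearchConfig = SearchConfig(),
) -> list[SiteMatch]:
    """Rank database structures by local-site similarity to the query.

    One best match per structure; matches are assigned add-one empirical
    P-values against *null* and E-values against len(db); only hits with
    E-value < ``config.e_cutoff`` are returned, sorted by (E-value, RMSD).
    """
    if len(db) == 0:
        raise ValueError("database is empty")
    subs = substitution_sets(site, config.score_cutoff)
    query_cm = contact_matrix(site)
    hits: list[SiteMatch] = []
    for target in db:
        m = best_match(site, target, subs, config, query_cm=query_cm)
        if m is None:
            continue
        m.p_value = p_value(null, m.rmsd)
        m.e_value = e_value(m.p_value, len(db))
        if m.e_value < config.e_cutoff:
            hits.append(m)
    hits.sort(key=lambda m: (m.e_value, m.rmsd, m.target_struct))
    return hits


def write_hit_table(hits: Sequence[SiteMatch], path) -> None:
    """Hit table TSV with the per-hit mapped residue list."""
    with open(path, "w") as fh:
        fh.write(
            "query_site_id\ttarget_struct\tn_mapped\tcmad\trmsd\tp_value\te_value\tmapped_residues\n"
        )
        for h in hits:
            mapped = ",".join(f"{r.res_name}{r.seq_id}" for _, r in h.mapping)
            fh.write(
                f"{h.query_site_id}\t{h.target_struct}\t{len(h.mapping)}\t"
                f"{h.cmad:.4f}\t{h.rmsd:.4f}\t{h.p_value:.6g}\t{h.e_value:.6g}\t{mapped}\n"
            )
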