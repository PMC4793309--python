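"""Independent brute-force oracles used to validate the fast implementations.

Each oracle is a direct, unoptimised transcription of the defining rule it
checks, sharing no code with the implementation under test.
"""

from itertools import combinations, permutations

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation


def pairwise_mean_abs_dev(coords_a, coords_b):
    """Mean |d_a(i,j) − d_b(i,j)| over i<j by explicit double loop."""
    n = len(coords_a)
    devs = []
    for i in range(n):
        for j in range(i + 1, n):
            da = np.linalg.norm(np.asarray(coords_a[i]) - np.asarray(coords_a[j]))
            db = np.linalg.norm(np.asarray(coords_b[i]) - np.asarray(coords_b[j]))
            devs.append(abs(da - db))
    return float(np.mean(devs))


def rotation_search_rmsd(a, b, coarse_deg=15.0):
    """Minimum superposition RMSD by Euler-grid search plus local refinement.

    Centres both point sets, scans a coarse Euler-angle grid, then refines the
    best grid point with Nelder-Mead over the rotation vector.  Independent of
    the closed-form solver it validates.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    ac = a - a.mean(axis=0)
    bc = b - b.mean(axis=0)

    def rmsd_of(rot):
        d = ac @ rot.as_matrix().T - bc
        return float(np.sqrt((d**2).sum() / len(a)))

    grid = np.deg2rad(np.arange(0.0, 360.0, coarse_deg))
    half = np.deg2rad(np.arange(0.0, 180.0 + coarse_deg, coarse_deg))
    best = (np.inf, None)
    for z1 in grid:
        for y in half:
            for z2 in grid:
                rot = Rotation.from_euler("zyz", [z1, y, z2])
                r = rmsd_of(rot)
                if r < best[0]:
                    best = (r, rot)

    def objective(v):
        return rmsd_of(Rotation.from_rotvec(v))

    res = minimize(
        objective, best[1].as_rotvec(), method="Nelder-Mead",
        options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 5000},
    )
    return float(res.fun)


def exhaustive_mappings(query_coords, query_codes, target_coords, target_codes,
                        allowed, pair_tol):
    """All injective code-compatible assignments passing the pairwise check.

    Brute force over permutations of target indices; feasible only for tiny
    instances.  Returns a sorted list of target-index tuples in query order.
    """
    n = len(query_codes)
    q = np.asarray(query_coords, dtype=float)
    t = np.asarray(target_coords, dtype=float)
    out = []
    for perm in permutations(range(len(target_codes)), n):
        if any(target_codes[perm[i]] not in allowed[i] for i in range(n)):
            continue
        ok = True
        for i in range(n):
            for j in range(i + 1, n):
                dq = np.linalg.norm(q[i] - q[j])
                dt = np.linalg.norm(t[perm[i]] - t[perm[j]])
                if abs(dt - dq) > pair_tol:
                    ok = False
                    break
            if not ok:
                break
        if ok:
            out.append(tuple(perm))
    return sorted(out)


def hypergeom_upper_tail(k, N, K, n):
    """P(X ≥ k) by exhaustive enumeration of all C(N, n) draws (N ≤ 12)."""
    universe = range(N)
    special = set(range(K))
    total = 0
    hits = 0
    for draw in combinations(universe, n):
        total += 1
        if len(special.intersection(draw)) >= k:
            hits += 1
    return hits / total


def bh_step_up(p_values):
    """Benjamini–Hochberg adjusted p-values from the step-up definition."""
    p = np.asarray(p_values, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    prev = 1.0
    for rank_from_end, idx in enumerate(order[::-1]):
        rank = m - rank_from_end
        val = min(prev, p[idx] * m / rank)
        adj[idx] = val
        prev = val
    return list(adj)


def greedy_cluster_count(sequences, identity_fn, cutoff):
    """Greedy longest-first clustering over the all-pairs identity matrix."""
    order = sorted(range(len(sequences)), key=lambda k: (-len(sequences[k]), k))
    reps = []
    for k in order:
        for r in reps:
            if identity_fn(sequences[k], sequences[r]) >= cutoff:
                break
        else:
            reps.append(k)
    return len(reps)
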