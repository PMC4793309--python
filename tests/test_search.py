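import numpy as np
import pytest
from scipy.spatial.transform import Rotation
from scipy.stats import ks_2samp

import pocketfish as pf
from pocketfish import synth
from pocketfish.search import best_match
from pocketfish.structures import ONE_TO_THREE

from .conftest import apply_rigid_to_structure, random_rigid_transform
from .oracles import exhaustive_mappings, pairwise_mean_abs_dev, rotation_search_rmsd

AA20 = "ACDEFGHIKLMNPQRSTVWY"


def _site_from_points(codes, points):
    res = [
        pf.Residue(
            chain_id="A", seq_id=i + 1, res_name=ONE_TO_THREE[c],
            atoms=[pf.Atom(name="CA", element="C", coord=p)],
        )
        for i, (c, p) in enumerate(zip(codes, points))
    ]
    return pf.BindingSite("toy-site", "TOY", "LIG", res, np.asarray(points, float), 5.0)


def _structure_from_points(codes, points, struct_id="TGT"):
    res = [
        pf.Residue(
            chain_id="A", seq_id=i + 1, res_name=ONE_TO_THREE[c],
            atoms=[pf.Atom(name="CA", element="C", coord=p)],
        )
        for i, (c, p) in enumerate(zip(codes, points))
    ]
    return pf.Structure(struct_id=struct_id, residues=res)


class TestSubstitutionSets:
    def test_tryptophan_neighbourhood(self):
        site = _site_from_points("W" * 3, np.eye(3) * 4)
        subs = pf.substitution_sets(site, score_cutoff=1)
        assert subs.allowed[0] == frozenset("WYF")

    def test_own_code_always_retained(self):
        site = _site_from_points("A" * 3, np.eye(3) * 4)
        subs = pf.substitution_sets(site, score_cutoff=5)
        assert subs.allowed[0] == frozenset("A")  # BLOSUM62 A/A = 4 < 5

    def test_low_cutoff_admits_everything(self):
        site = _site_from_points("AWC", np.eye(3) * 4)
        subs = pf.substitution_sets(site, score_cutoff=-10)
        assert all(s == frozenset(AA20) for s in subs.allowed)


class TestCmad:
    def test_identical_coordinates(self, query_site):
        cm = pf.contact_matrix(query_site)
        assert pf.cmad(cm, query_site.rep_coords) == pytest.approx(0.0)

    def test_uniform_offset_triangle(self):
        # equilateral triangles with sides 3 and 4: every pair deviates by 1
        def tri(side):
            return side * np.array([[0, 0, 0], [1, 0, 0], [0.5, np.sqrt(3) / 2, 0]])

        site = _site_from_points("AAA", tri(3.0))
        cm = pf.contact_matrix(site)
        assert pf.cmad(cm, tri(4.0)) == pytest.approx(1.0)

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(2)
        a = rng.normal(scale=5, size=(4, 3))
        b = rng.normal(scale=5, size=(4, 3))
        site = _site_from_points("ACDE", a)
        cm = pf.contact_matrix(site)
        assert pf.cmad(cm, b) == pytest.approx(pairwise_mean_abs_dev(a, b))

    def test_size_mismatch(self, query_site):
        cm = pf.contact_matrix(query_site)
        with pytest.raises(ValueError):
            pf.cmad(cm, np.zeros((2, 3)))


class TestKabsch:
    def test_recovers_rigid_copy(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=(6, 3))
        R, t = random_rigid_transform(rng)
        b = a @ R.T + t
        tr, rmsd = pf.kabsch(a, b)
        assert rmsd <= 1e-6
        np.testing.assert_allclose(tr.apply(a), b, atol=1e-6)

    def test_mirror_image_not_matched_by_reflection(self):
        a = np.array([[0, 0, 0], [1.5, 0, 0], [0, 2.0, 0], [0, 0, 2.5]])  # chiral
        b = a.copy()
        b[:, 0] *= -1
        tr, rmsd = pf.kabsch(a, b)
        assert rmsd > 0.1
        assert np.linalg.det(tr.rotation) == pytest.approx(1.0, abs=1e-8)

    def test_matches_rotation_grid_search(self):
        rng = np.random.default_rng(4)
        a = rng.normal(scale=3, size=(5, 3))
        b = rng.normal(scale=3, size=(5, 3))
        _, rmsd = pf.kabsch(a, b)
        assert rmsd == pytest.approx(rotation_search_rmsd(a, b), abs=1e-4)

    def test_agrees_with_scipy_align_vectors(self):
        rng = np.random.default_rng(6)
        a = rng.normal(scale=3, size=(8, 3))
        b = rng.normal(scale=3, size=(8, 3))
        _, rmsd = pf.kabsch(a, b)
        rot, rssd = Rotation.align_vectors(b - b.mean(0), a - a.mean(0))
        assert rmsd == pytest.approx(rssd / np.sqrt(len(a)), abs=1e-8)

    def test_rank_zero_rejected(self):
        pts = np.zeros((4, 3))
        with pytest.raises(ValueError):
            pf.kabsch(pts, pts)


class TestEnumerateCandidates:
    def test_planted_copy_found(self, query_site):
        rng = np.random.default_rng(8)
        n_extra = 20
        extra = rng.normal(scale=20, size=(n_extra, 3)) + 60
        codes = query_site.codes + "".join(rng.choice(list(AA20), size=n_extra))
        points = np.vstack([query_site.rep_coords, extra])
        target = _structure_from_points(codes, points)
        subs = pf.substitution_sets(query_site, 1)
        cands = pf.enumerate_candidates(query_site, target, subs, pair_tol=2.0)
        assert tuple(range(query_site.size)) in cands.mappings

    def test_incompatible_codes_yield_nothing(self):
        site = _site_from_points("WWW", [[0, 0, 0], [5, 0, 0], [0, 5, 0]])
        target = _structure_from_points("DDDD", np.eye(4, 3) * 5)
        subs = pf.substitution_sets(site, 1)
        assert pf.enumerate_candidates(site, target, subs).mappings == []

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(12)
        q_codes = "ACDE"
        q_pts = rng.normal(scale=4, size=(4, 3))
        t_codes = "".join(rng.choice(list(AA20), size=12))
        t_pts = rng.normal(scale=5, size=(12, 3))
        site = _site_from_points(q_codes, q_pts)
        target = _structure_from_points(t_codes, t_pts)
        subs = pf.substitution_sets(site, 1)
        got = pf.enumerate_candidates(site, target, subs, pair_tol=2.0).mappings
        expected = exhaustive_mappings(q_pts, q_codes, t_pts, t_codes, subs.allowed, 2.0)
        assert got == expected

    def test_cap_flags_truncation_and_keeps_subset(self):
        # highly symmetric target: many self-consistent mappings
        pts = np.array([[i * 4.0, j * 4.0, 0.0] for i in range(4) for j in range(4)])
        site = _site_from_points("AAA", pts[:3])
        target = _structure_from_points("A" * 16, pts)
        subs = pf.substitution_sets(site, 1)
        full = pf.enumerate_candidates(site, target, subs, pair_tol=0.5, max_candidates=10_000)
        capped = pf.enumerate_candidates(site, target, subs, pair_tol=0.5, max_candidates=5)
        assert capped.truncated and not full.truncated
        assert set(capped.mappings) <= set(full.mappings)
        # raising the cap never loses the best CMAD seen at the lower cap
        cm = pf.contact_matrix(site)
        best_low = min(pf.cmad(cm, pts[list(m)]) for m in capped.mappings)
        best_high = min(pf.cmad(cm, pts[list(m)]) for m in full.mappings)
        assert best_high <= best_low + 1e-12


class TestNullAndPValues:
    def test_determinism(self, query_site):
        decoys = synth.make_decoy_db(5, 3, n_res=40)
        n1 = pf.calibrate_null(query_site, decoys, n_samples=200, seed=5)
        n2 = pf.calibrate_null(query_site, decoys, n_samples=200, seed=5)
        np.testing.assert_array_equal(n1.rmsd_samples, n2.rmsd_samples)

    def test_two_seed_distribution_consistency(self, query_site):
        decoys = synth.make_decoy_db(8, 21, n_res=50)
        n1 = pf.calibrate_null(query_site, decoys, n_samples=1000, seed=1)
        n2 = pf.calibrate_null(query_site, decoys, n_samples=1000, seed=2)
        ks = ks_2samp(n1.rmsd_samples, n2.rmsd_samples).statistic
        assert ks <= 0.08

    def test_add_one_formula(self):
        null = pf.NullModel(
            n_samples=999, rmsd_samples=np.linspace(1.0, 10.0, 999), seed=0, site_size=5
        )
        assert pf.p_value(null, 0.5) == pytest.approx(1 / 1000)
        assert pf.p_value(null, 11.0) == pytest.approx(1.0)
        assert pf.e_value(0.001, 100) == pytest.approx(0.1)

    def test_p_monotone_in_rmsd(self):
        rng = np.random.default_rng(0)
        null = pf.NullModel(
            n_samples=500, rmsd_samples=np.sort(rng.exponential(2, 500)), seed=0, site_size=5
        )
        xs = np.linspace(0, 10, 50)
        ps = [pf.p_value(null, x) for x in xs]
        assert all(b >= a for a, b in zip(ps, ps[1:]))


class TestSearch:
    def test_self_recovery_tops_ranking(self, query_complex, query_site):
        decoys = synth.make_decoy_db(10, 31, n_res=60)
        db = pf.StructureDB(structures=[query_complex] + list(decoys.structures))
        null = pf.calibrate_null(query_site, synth.make_decoy_db(6, 77, n_res=60),
                                 n_samples=2000, seed=8)
        hits = pf.search(query_site, db, null, pf.SearchConfig())
        assert hits and hits[0].target_struct == query_complex.struct_id
        assert hits[0].cmad == pytest.approx(0.0, abs=1e-9)
        assert hits[0].rmsd == pytest.approx(0.0, abs=1e-9)

    def test_rigid_motion_invariance_of_scores(self, query_site, query_complex):
        subs = pf.substitution_sets(query_site, 1)
        cfg = pf.SearchConfig()
        m1 = best_match(query_site, query_complex, subs, cfg)
        rng = np.random.default_rng(19)
        R, t = random_rigid_transform(rng)
        moved = apply_rigid_to_structure(query_complex, R, t)
        m2 = best_match(query_site, moved, subs, cfg)
        assert m1.cmad == pytest.approx(m2.cmad, abs=1e-6)
        assert m1.rmsd == pytest.approx(m2.rmsd, abs=1e-6)

    def test_empty_database_rejected(self, query_site):
        null = pf.NullModel(
            n_samples=100, rmsd_samples=np.linspace(1, 5, 100), seed=0,
            site_size=query_site.size,
        )
        with pytest.raises(ValueError):
            pf.search(query_site, pf.StructureDB(structures=[]), null)

    def test_hit_table_export(self, tmp_path, query_site, benchmark, benchmark_hits):
        out = tmp_path / "hits.tsv"
        from pocketfish.search import write_hit_table

        write_hit_table(benchmark_hits, out)
        lines = out.read_text().strip().splitlines()
        assert len(lines) == len(benchmark_hits) + 1
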