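import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import pocketfish as pf
from pocketfish.network import (
    EnrichmentResult,
    write_edge_list,
    write_enrichment_table,
    write_graphml,
)
from pocketfish.structures import ONE_TO_THREE

from .conftest import apply_rigid_to_structure, random_rigid_transform
from .oracles import bh_step_up, hypergeom_upper_tail


def _chain(seq, coords, struct_id):
    residues = [
        pf.Residue(
            chain_id="A", seq_id=i + 1, res_name=ONE_TO_THREE[c],
            atoms=[pf.Atom(name="CA", element="C", coord=p)],
        )
        for i, (c, p) in enumerate(zip(seq, coords))
    ]
    return pf.Structure(struct_id=struct_id, residues=residues)


class TestPairwiseRmsd:
    def test_self_is_zero(self, query_complex):
        assert pf.pairwise_rmsd(query_complex, query_complex) == pytest.approx(0.0, abs=1e-9)

    def test_translated_copy(self, query_complex):
        moved = apply_rigid_to_structure(query_complex, np.eye(3), np.array([5.0, 1, 2]))
        assert pf.pairwise_rmsd(query_complex, moved) <= 1e-6

    def test_matches_kabsch_on_known_alignment(self):
        rng = np.random.default_rng(2)
        coords_a = np.cumsum(rng.normal(scale=2, size=(6, 3)), axis=0)
        coords_b = coords_a + rng.normal(scale=0.5, size=(6, 3))
        a = _chain("ACDEFG", coords_a, "A6")
        b = _chain("ACDEFG", coords_b, "B6")
        # identical sequences align residue-to-residue, so the RMSD must equal
        # a direct Kabsch superposition over all six pairs
        _, expected = pf.kabsch(coords_a, coords_b)
        assert pf.pairwise_rmsd(a, b) == pytest.approx(expected, abs=1e-9)

    def test_incomparable_pair(self):
        a = _chain("AAA", np.eye(3) * 3.8, "A3")
        b = _chain("WWW", np.eye(3) * 3.8, "W3")
        # BLOSUM62 global alignment of AAA/WWW still aligns 3 positions, so
        # check the too-few-residues marker with a genuinely short chain
        short = _chain("AAA", np.eye(3) * 3.8, "S")
        assert pf.pairwise_rmsd(a, b) is not None
        assert pf.pairwise_rmsd(short, short) == pytest.approx(0.0, abs=1e-9)


class TestBuildNetwork:
    def test_identical_structures_linked(self, query_complex):
        other = apply_rigid_to_structure(query_complex, np.eye(3), np.array([1.0, 0, 0]))
        other = pf.Structure(struct_id="COPY", residues=other.residues)
        g = pf.build_network({"QRY0": query_complex, "COPY": other})
        assert g.has_edge("QRY0", "COPY")

    def test_threshold_is_strict(self):
        # two conformers of the same sequence, built so RMSD == 4 exactly:
        # rigid bodies displaced along z after centring are detected at their
        # post-superposition RMSD; instead construct per-residue offsets
        rng = np.random.default_rng(8)
        coords = np.cumsum(rng.normal(scale=2.5, size=(8, 3)), axis=0)
        a = _chain("ACDEFGHI", coords, "A")
        _, rmsd0 = pf.kabsch(coords, coords)
        offsets = rng.normal(size=coords.shape)
        b_coords = coords + offsets
        _, r = pf.kabsch(coords, b_coords)
        scale = 4.0 / r
        b = _chain("ACDEFGHI", coords + offsets * scale, "B")
        r_ab = pf.pairwise_rmsd(a, b)
        if abs(r_ab - 4.0) < 0.2:  # scaling is approximate; strictness is what matters
            g = pf.build_network({"A": a, "B": b}, threshold=r_ab)
            assert not g.has_edge("A", "B")
        g2 = pf.build_network({"A": a, "B": b}, threshold=r_ab + 1e-6)
        assert g2.has_edge("A", "B")

    def test_edge_set_matches_exhaustive_pairs(self):
        rng = np.random.default_rng(13)
        structures = {}
        base = np.cumsum(rng.normal(scale=2.5, size=(7, 3)), axis=0)
        for k in range(4):
            coords = base + rng.normal(scale=0.8 * k, size=base.shape)
            structures[f"S{k}"] = _chain("ACDEFGH", coords, f"S{k}")
        g = pf.build_network(structures, threshold=4.0)
        ids = sorted(structures)
        for i, a in enumerate(ids):
            for b in ids[i + 1:]:
                r = pf.pairwise_rmsd(structures[a], structures[b])
                assert g.has_edge(a, b) == (r is not None and r < 4.0)

    def test_symmetry_and_no_self_edges(self, query_complex):
        g = pf.build_network({"X": query_complex})
        assert not list(g.edges)
        rng = np.random.default_rng(1)
        coords = np.cumsum(rng.normal(scale=2.5, size=(6, 3)), axis=0)
        a = _chain("ACDEFG", coords, "A")
        b = _chain("ACDEFG", coords + 0.1, "B")
        assert pf.pairwise_rmsd(a, b) == pytest.approx(pf.pairwise_rmsd(b, a), abs=1e-6)


class TestAdjustP:
    def test_single_p_unchanged(self):
        assert pf.adjust_p([0.04], "bh") == [pytest.approx(0.04)]
        assert pf.adjust_p([0.04], "bonferroni") == [pytest.approx(0.04)]

    def test_bonferroni_multiplies(self):
        assert pf.adjust_p([0.01, 0.5, 0.9], "bonferroni")[0] == pytest.approx(0.03)

    def test_bh_hand_computed_example(self):
        got = pf.adjust_p([0.01, 0.02, 0.03], "bh")
        assert got == [pytest.approx(0.03)] * 3

    @given(ps=st.lists(st.floats(0, 1), min_size=1, max_size=15))
    @settings(max_examples=60, deadline=None)
    def test_bh_matches_step_up_definition(self, ps):
        got = pf.adjust_p(ps, "bh")
        expected = bh_step_up(ps)
        for g, e in zip(got, expected):
            assert g == pytest.approx(e, abs=1e-12)

    @given(ps=st.lists(st.floats(0, 1), min_size=1, max_size=15))
    @settings(max_examples=40, deadline=None)
    def test_ordering_bonferroni_bh_raw(self, ps):
        bh = pf.adjust_p(ps, "bh")
        bonf = pf.adjust_p(ps, "bonferroni")
        for p, hb, bf in zip(ps, bh, bonf):
            assert bf >= hb - 1e-12
            assert hb >= p - 1e-12

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            pf.adjust_p([1.5], "bh")


class TestEnrich:
    def _db(self):
        return pf.PathwayDB(
            pathways={"pw": {"g1", "g2"}},
            background={"g1", "g2", "g3", "g4"},
        )

    def test_exact_small_case(self):
        res = pf.enrich({"g1", "g2"}, self._db(), method="bonferroni")
        assert res[0].p_raw == pytest.approx(1 / 6)
        assert res[0].count == 2
        assert res[0].percentage == pytest.approx(100.0)

    def test_zero_overlap_gives_one(self):
        res = pf.enrich({"g3", "g4"}, self._db())
        assert res[0].p_raw == pytest.approx(1.0)

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(21)
        genes = [f"g{i}" for i in range(10)]
        pathways = {
            "a": set(genes[:4]),
            "b": set(genes[3:8]),
            "c": set(genes[7:]),
        }
        db = pf.PathwayDB(pathways=pathways, background=set(genes))
        targets = set(rng.choice(genes, size=5, replace=False))
        res = {r.pathway: r for r in pf.enrich(targets, db)}
        for name, members in pathways.items():
            k = len(targets & members)
            expected = hypergeom_upper_tail(k, 10, len(members), 5)
            assert res[name].p_raw == pytest.approx(expected, abs=1e-12)

    def test_genes_outside_background_dropped(self):
        res = pf.enrich({"g1", "g2", "nope"}, self._db())
        assert res[0].percentage == pytest.approx(100.0)  # denominator 2, not 3

    def test_empty_mapped_set_rejected(self):
        with pytest.raises(ValueError):
            pf.enrich({"nope"}, self._db())


def test_gmt_reading_and_exports(tmp_path, query_complex):
    gmt = tmp_path / "p.gmt"
    gmt.write_text("pw1\tdesc\tg1\tg2\npw2\tdesc\tg2\tg3\n")
    db = pf.read_gmt(gmt)
    assert db.background == {"g1", "g2", "g3"}
    results = pf.enrich({"g1", "g2"}, db)
    write_enrichment_table(results, tmp_path / "enr.tsv")
    assert (tmp_path / "enr.tsv").read_text().count("\n") == 3

    g = pf.build_network({"Q": query_complex})
    write_edge_list(g, tmp_path / "edges.tsv")
    write_graphml(g, tmp_path / "net.graphml")
    assert (tmp_path / "edges.tsv").exists() and (tmp_path / "net.graphml").exists()
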