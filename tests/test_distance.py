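"""Gower dissimilarity, Cailliez-corrected PCoA, UPGMA, minimum spanning tree."""

import itertools

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from traitdiv import (
    DissimilarityMatrix,
    TraitSchema,
    ValidationError,
    cailliez_constant,
    gower,
    mst,
    pcoa_cailliez,
    upgma,
)
from traitdiv.distance import mst_edges

from conftest import gower_by_hand, make_traits


class TestGower:
    def test_identical_trait_rows_have_zero_distance(self, mini_schema):
        t = make_traits(mini_schema, {
            "a": [10.0, 1, 0, 0, 0, 1, 0, 0, "high"],
            "b": [10.0, 1, 0, 0, 0, 1, 0, 0, "low"],
            "c": [99.0, 0, 1, 1, 0, 0, 1, 1, "low"],
        })
        d = gower(t)
        assert d.values[0, 1] == 0.0

    def test_fully_opposite_species_reach_maximal_distance(self, mini_schema):
        # masses span the pool range; every binary trait differs -> d = 1
        t = make_traits(mini_schema, {
            "tiny": [2.0, 1, 0, 1, 0, 1, 0, 1, "high"],
            "huge": [2172.0, 0, 1, 0, 1, 0, 1, 0, "low"],
        })
        d = gower(t)
        assert d.values[0, 1] == pytest.approx(1.0)

    def test_matches_per_trait_hand_computation(self, mini_traits):
        np.testing.assert_allclose(
            gower(mini_traits).values, gower_by_hand(mini_traits), atol=1e-12
        )

    def test_invariant_to_species_and_column_order(self, mini_traits):
        d = gower(mini_traits)
        perm = [3, 1, 5, 0, 2, 4]
        shuffled_rows = mini_traits.data.iloc[perm]
        cols = list(shuffled_rows.columns)
        rng = np.random.default_rng(1)
        shuffled = type(mini_traits)(
            shuffled_rows[rng.permutation(cols)], mini_traits.schema
        )
        d2 = gower(shuffled)
        idx = d.index_of(list(shuffled.species))
        np.testing.assert_allclose(d2.values, d.values[np.ix_(idx, idx)], atol=1e-12)

    def test_binary_only_equals_simple_matching(self, mini_schema):
        schema = TraitSchema(continuous=(), binary=dict(mini_schema.binary))
        t = make_traits(schema, {
            "a": [1, 0, 0, 0, 1, 0, 0, "high"],
            "b": [1, 1, 0, 0, 0, 1, 0, "low"],
            "c": [0, 1, 1, 0, 0, 1, 1, "low"],
        })
        d = gower(t)
        B = t.binary_matrix.to_numpy(float)
        expected = cdist(B, B, metric="cityblock") / B.shape[1]
        np.testing.assert_allclose(d.values, expected, atol=1e-12)

    def test_pool_range_reused_for_subsets(self, mini_traits):
        pool_ranges = mini_traits.continuous_ranges()
        sub = type(mini_traits)(mini_traits.data.iloc[:3], mini_traits.schema)
        d_sub = gower(sub, ranges=pool_ranges)
        d_pool = gower(mini_traits)
        np.testing.assert_allclose(d_sub.values, d_pool.values[:3, :3], atol=1e-12)

    def test_zero_continuous_range_rejected(self, mini_schema):
        t = make_traits(mini_schema, {
            "a": [10.0, 1, 0, 0, 0, 1, 0, 0, "high"],
            "b": [10.0, 0, 1, 0, 0, 0, 1, 0, "low"],
        })
        with pytest.raises(ValidationError, match="zero range"):
            gower(t)

    def test_asymmetric_binary_drops_double_absences(self, mini_schema):
        schema = TraitSchema(
            continuous=(), binary=dict(mini_schema.binary), asymmetric_binary=True
        )
        t = make_traits(schema, {
            "a": [1, 0, 0, 0, 1, 0, 0, "high"],
            "b": [1, 1, 0, 0, 1, 0, 0, "low"],
        })
        # informative traits: invertebrates (match), fruits (mismatch), canopy
        # (match); 4 double absences dropped -> d = 1/3
        assert gower(t).values[0, 1] == pytest.approx(1 / 3)


class TestCailliez:
    def test_euclidean_input_needs_no_correction(self):
        # 3 collinear points at 0, 1, 2
        d = DissimilarityMatrix(
            ("a", "b", "c"),
            np.array([[0, 1, 2], [1, 0, 1], [2, 1, 0]], dtype=float),
        )
        space = pcoa_cailliez(d)
        assert space.cailliez_constant == 0.0
        rec = cdist(space.coordinates, space.coordinates)
        np.testing.assert_allclose(rec, d.values, atol=1e-8)

    def test_non_euclidean_star_gets_known_constant(self):
        # hub at distance 1 from three mutually-distance-2 points: the
        # circumradius of the outer triangle exceeds 1, so not embeddable
        v = np.array([
            [0, 1, 1, 1],
            [1, 0, 2, 2],
            [1, 2, 0, 2],
            [1, 2, 2, 0],
        ], dtype=float)
        c = cailliez_constant(v)
        assert c == pytest.approx(0.3660254037844386, abs=1e-10)
        space = pcoa_cailliez(DissimilarityMatrix(("h", "x", "y", "z"), v))
        rec = cdist(space.coordinates, space.coordinates)
        expected = v + c
        np.fill_diagonal(expected, 0.0)
        np.testing.assert_allclose(rec, expected, atol=1e-8)

    def test_corrected_eigenvalues_nonnegative(self, mini_traits):
        space = pcoa_cailliez(gower(mini_traits))
        assert space.eigenvalues.min() >= -1e-8
        assert (np.diff(space.eigenvalues) <= 1e-12).all()


class TestUpgma:
    def test_pair_merges_at_their_distance(self):
        d = DissimilarityMatrix(("a", "b"), np.array([[0, 0.6], [0.6, 0]]))
        dend = upgma(d)
        assert dend.heights.tolist() == [0.6]
        assert dend.edge_lengths().sum() == pytest.approx(1.2)

    def test_three_species_average_linkage(self):
        d = DissimilarityMatrix(
            ("A", "B", "C"),
            np.array([[0, 0.2, 0.8], [0.2, 0, 0.8], [0.8, 0.8, 0]]),
        )
        dend = upgma(d)
        np.testing.assert_allclose(dend.heights, [0.2, 0.8])
        # cophenetic: d(A,B) = 0.2, both to C at 0.8
        coph = dend.cophenetic()
        i = {s: k for k, s in enumerate(dend.ids)}
        assert coph[i["A"], i["B"]] == pytest.approx(0.2)
        assert coph[i["A"], i["C"]] == pytest.approx(0.8)

    def test_cophenetic_distances_are_ultrametric(self):
        rng = np.random.default_rng(5)
        pts = rng.random((8, 3))
        v = cdist(pts, pts)
        dend = upgma(DissimilarityMatrix(tuple("abcdefgh"), v))
        coph = dend.cophenetic()
        n = 8
        for i, j, k in itertools.combinations(range(n), 3):
            assert coph[i, j] <= max(coph[i, k], coph[j, k]) + 1e-10
        assert (np.diff(dend.heights) >= -1e-12).all()

    def test_newick_export_has_all_leaves(self, mini_traits):
        dend = upgma(gower(mini_traits))
        nwk = dend.to_newick()
        assert nwk.endswith(";")
        for sp in mini_traits.species:
            assert sp in nwk
        assert nwk.count("(") == nwk.count(")")


def brute_force_mst_length(dist: np.ndarray) -> float:
    """Minimum total length over all spanning trees, by enumeration."""
    n = dist.shape[0]
    all_edges = list(itertools.combinations(range(n), 2))
    best = np.inf
    for subset in itertools.combinations(all_edges, n - 1):
        # connectivity check by union-find
        parent = list(range(n))

        def find(u):
            while parent[u] != u:
                parent[u] = parent[parent[u]]
                u = parent[u]
            return u

        ok = True
        for u, v in subset:
            ru, rv = find(u), find(v)
            if ru == rv:
                ok = False
                break
            parent[ru] = rv
        if ok:
            best = min(best, sum(dist[u, v] for u, v in subset))
    return best


class TestMst:
    def test_collinear_points_use_short_edges(self):
        pts = np.array([[0.0], [1.0], [2.0]])
        edges = mst(pts)
        total = sum(w for _, _, w in edges)
        assert total == pytest.approx(2.0)
        assert all(w == pytest.approx(1.0) for _, _, w in edges)

    @pytest.mark.parametrize("n,seed", [(5, 0), (6, 1), (6, 2)])
    def test_total_length_matches_brute_force(self, n, seed):
        rng = np.random.default_rng(seed)
        pts = rng.random((n, 2))
        dist = cdist(pts, pts)
        edges = mst_edges(dist)
        assert len(edges) == n - 1
        total = sum(w for _, _, w in edges)
        assert total == pytest.approx(brute_force_mst_length(dist), abs=1e-12)

    def test_duplicated_point_keeps_zero_length_edge(self):
        pts = np.array([[0.0, 0.0], [0.0, 0.0], [3.0, 4.0]])
        edges = mst(pts)
        assert len(edges) == 2
        lengths = sorted(w for _, _, w in edges)
        assert lengths[0] == 0.0
        assert lengths[1] == pytest.approx(5.0)
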