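import math

import numpy as np
import pandas as pd
import pytest

from clustercall import (
    UNASSIGNED,
    ClusterMetadata,
    ExpressionMatrix,
    MarkerTable,
    clustify_lists,
    gsea_score,
    hypergeom_enrich,
    jaccard,
    pct_detection,
    rank_cluster_markers,
)
from clustercall.enrichment import gsea_running_sum


def exact_hypergeom_tail(M, a, b, k):
    """Brute-force upper tail by explicit combinatorial summation."""
    total = 0
    for i in range(k, min(a, b) + 1):
        total += math.comb(b, i) * math.comb(M - b, a - i)
    return total / math.comb(M, a)


class TestHypergeom:
    def test_zero_overlap_is_certain(self):
        a = {f"a{i}" for i in range(4)}
        b = {f"b{i}" for i in range(4)}
        assert hypergeom_enrich(a, b, 10_000) == pytest.approx(1.0)

    def test_full_overlap_closed_form(self):
        s = {f"g{i}" for i in range(5)}
        # single-term tail: 1 / C(20, 5)
        assert hypergeom_enrich(s, set(s), 20) == pytest.approx(1 / 15504, rel=1e-12)

    def test_partial_overlap_matches_enumeration(self):
        a = {f"s{i}" for i in range(5)} | {f"a{i}" for i in range(5)}
        b = {f"s{i}" for i in range(5)} | {f"b{i}" for i in range(5)}
        want = exact_hypergeom_tail(100, 10, 10, 5)
        assert hypergeom_enrich(a, b, 100) == pytest.approx(want, rel=1e-12)

    def test_non_increasing_in_overlap(self):
        universe = 50
        prev = None
        for k in range(0, 9):
            a = {f"s{i}" for i in range(k)} | {f"a{i}" for i in range(8 - k)}
            b = {f"s{i}" for i in range(k)} | {f"b{i}" for i in range(8 - k)}
            p = hypergeom_enrich(a, b, universe)
            if prev is not None:
                assert p <= prev + 1e-15
            prev = p

    def test_universe_smaller_than_union_raises(self):
        with pytest.raises(ValueError, match="universe"):
            hypergeom_enrich({"a", "b"}, {"c", "d"}, 3)


class TestJaccard:
    def test_identical_sets(self):
        assert jaccard({"a", "b"}, {"a", "b"}) == 1.0

    def test_disjoint_sets(self):
        assert jaccard({"a"}, {"b"}) == 0.0

    def test_enumerated_example(self):
        assert jaccard({"a", "b", "c"}, {"b", "c", "d"}) == pytest.approx(0.5)

    def test_symmetric_and_bounded(self):
        rng = np.random.default_rng(0)
        pool = [f"g{i}" for i in range(30)]
        for _ in range(25):
            a = set(rng.choice(pool, rng.integers(1, 20), replace=False))
            b = set(rng.choice(pool, rng.integers(1, 20), replace=False))
            j = jaccard(a, b)
            assert j == jaccard(b, a)
            assert 0.0 <= j <= 1.0

    def test_both_empty_warns_and_returns_zero(self):
        with pytest.warns(UserWarning):
            assert jaccard(set(), set()) == 0.0


class TestPctDetection:
    def _fixture(self):
        # cluster A: g0 in all 4 cells, g1 in 2/4; cluster B: g0 in none
        values = pd.DataFrame(
            {
                "c0": [1.0, 1.0, 0.5],
                "c1": [0.3, 1.0, 0.0],
                "c2": [2.0, 0.0, 0.0],
                "c3": [0.1, 0.0, 0.0],
                "d0": [0.0, 1.0, 0.2],
                "d1": [0.0, 0.0, 0.0],
            },
            index=["g0", "g1", "g2"],
        )
        mat = ExpressionMatrix(values)
        meta = ClusterMetadata(
            pd.DataFrame({"cluster": ["A"] * 4 + ["B"] * 2}, index=values.columns)
        )
        return mat, meta

    def test_mean_over_genes_of_cell_fractions(self):
        mat, meta = self._fixture()
        out = pct_detection(mat, meta, ["g0", "g1"])
        assert out["A"] == pytest.approx((1.0 + 0.5) / 2)
        assert out["B"] == pytest.approx((0.0 + 0.5) / 2)

    def test_absent_genes_error(self):
        mat, meta = self._fixture()
        with pytest.raises(ValueError, match="none of the listed genes"):
            pct_detection(mat, meta, ["nope"])


class TestGsea:
    def test_hand_computed_running_sum(self):
        # 10 genes, scores 10..1, set = ranks 1, 2 and 5
        scores = pd.Series(
            np.arange(10, 0, -1, dtype=float), index=[f"g{i}" for i in range(10)]
        )
        gene_set = ["g0", "g1", "g4"]
        es, running = gsea_running_sum(scores, gene_set)
        # hit weights 10, 9, 6 (sum 25); misses decrement 1/7
        w = np.array([10, 9, 0, 0, 6, 0, 0, 0, 0, 0]) / 25.0
        miss = np.array([0, 0, 1, 1, 0, 1, 1, 1, 1, 1]) / 7.0
        expected = np.cumsum(w - miss)
        np.testing.assert_allclose(running, expected, atol=1e-12)
        assert es == pytest.approx(expected[np.argmax(np.abs(expected))])

    def test_top_concentrated_set_has_positive_es_and_tiny_p(self):
        scores = pd.Series(
            np.linspace(5, 0.1, 60), index=[f"g{i:02d}" for i in range(60)]
        )
        gene_set = [f"g{i:02d}" for i in range(6)]  # the top 6 ranks
        es, p = gsea_score(scores, gene_set, n_perm=500, seed=3)
        assert es > 0.8
        assert p <= 1 / 500 + 0.01

    def test_es_ignores_labels_outside_the_set(self):
        scores = pd.Series([5.0, 4.0, 3.0, 2.0, 1.0], index=list("abcde"))
        relabeled = pd.Series(scores.to_numpy(), index=["a", "b", "x", "y", "z"])
        es1, _ = gsea_running_sum(scores.sort_values(ascending=False), ["a", "b"])
        es2, _ = gsea_running_sum(relabeled.sort_values(ascending=False), ["a", "b"])
        assert es1 == pytest.approx(es2)

    def test_deterministic_for_fixed_seed(self):
        rng = np.random.default_rng(8)
        scores = pd.Series(rng.normal(size=50), index=[f"g{i}" for i in range(50)])
        gene_set = [f"g{i}" for i in range(0, 50, 7)]
        assert gsea_score(scores, gene_set, n_perm=200, seed=5) == gsea_score(
            scores, gene_set, n_perm=200, seed=5
        )

    def test_random_sets_give_small_es_uniform_p(self):
        # sanity: under the null the permutation p-value is roughly uniform
        rng = np.random.default_rng(12)
        scores = pd.Series(rng.normal(size=80), index=[f"g{i}" for i in range(80)])
        ps = []
        for rep in range(60):
            gene_set = list(rng.choice(scores.index, 8, replace=False))
            _, p = gsea_score(scores, gene_set, n_perm=200, seed=rep)
            ps.append(p)
        assert 0.25 < np.mean(ps) < 0.75

    def test_empty_intersection_errors(self):
        scores = pd.Series([3.0, 2.0, 1.0], index=list("abc"))
        with pytest.raises(ValueError, match="intersect"):
            gsea_score(scores, ["zz"], n_perm=100, seed=0)


class TestClustifyLists:
    def test_identical_markers_win_under_jaccard(self):
        ref = MarkerTable({"B": ["g1", "g2", "g3"], "T": ["g4", "g5", "g6"]})
        query = MarkerTable({"q0": ["g1", "g2", "g3"]})
        scores, calls = clustify_lists(query, ref, metric="jaccard")
        assert scores.loc["q0", "B"] == pytest.approx(1.0)
        assert calls.call_for("q0") == "B"

    def test_no_overlap_unassigned_under_hypergeom(self):
        ref = MarkerTable({"B": ["g1", "g2"], "T": ["g3", "g4"]})
        query = MarkerTable({"q0": ["x1", "x2"], "q1": ["y1", "y2"]})
        scores, calls = clustify_lists(query, ref, metric="hypergeom", universe_n=5000)
        assert (calls.called_types == UNASSIGNED).all()
        assert (scores.to_numpy() <= 1e-9).all()  # -log10(1) = 0

    @pytest.mark.parametrize("metric", ["hypergeom", "jaccard", "pct", "gsea"])
    def test_planted_markers_recover_types(self, metric, default_dataset):
        query, meta, _, ref_markers = default_dataset
        query_markers = rank_cluster_markers(query, meta, n_markers=50)
        scores, calls = clustify_lists(
            query_markers, ref_markers, metric=metric, mat=query, meta=meta, seed=0
        )
        for cluster in calls.cluster_labels:
            assert calls.call_for(cluster) == cluster

    def test_unknown_metric_errors(self):
        ref = MarkerTable({"B": ["g1"]})
        with pytest.raises(ValueError, match="unknown metric"):
            clustify_lists(ref, ref, metric="euclid")
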