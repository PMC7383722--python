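import numpy as np
import pandas as pd
import pytest

from clustercall import (
    UNASSIGNED,
    CallTable,
    ClusterMetadata,
    ReferenceMatrix,
    benchmark_calls,
    cluster_accuracy,
    cor_to_call,
    clustify,
    filter_small_clusters,
    overcluster_test,
    per_type_f1,
    select_top_variance_genes,
)
from clustercall.synthetic import SyntheticSpec, generate_dataset


def _meta(sizes: dict[str, int]):
    clusters = [label for label, n in sizes.items() for _ in range(n)]
    cells = [f"c{i}" for i in range(len(clusters))]
    return ClusterMetadata(pd.DataFrame({"cluster": clusters}, index=cells))


def _calls(mapping, score=0.9):
    df = pd.DataFrame(
        [(c, t, score, 0.5) for c, t in mapping.items()],
        columns=["cluster", "type", "score", "threshold"],
    )
    return CallTable(df.set_index("cluster"))


class TestFilterSmallClusters:
    def test_default_warns_on_clusters_below_ten_cells(self):
        meta = _meta({"big": 50, "tiny": 9})
        with pytest.warns(UserWarning, match="tiny"):
            kept, messages = filter_small_clusters(meta)
        assert kept == ["big", "tiny"]  # warn but retain
        assert len(messages) == 1 and "9 cells" in messages[0]

    def test_strict_mode_drops_small_clusters(self):
        meta = _meta({"big": 50, "tiny": 9})
        with pytest.warns(UserWarning):
            kept, _ = filter_small_clusters(meta, strict=True)
        assert kept == ["big"]

    def test_min_cells_one_flags_nothing(self):
        kept, messages = filter_small_clusters(_meta({"a": 3, "b": 1}), min_cells=1)
        assert kept == ["a", "b"] and messages == []

    def test_fifteen_cell_clusters_pass_default(self):
        kept, messages = filter_small_clusters(_meta({"a": 15, "b": 15}))
        assert messages == []


class TestPerTypeF1:
    def test_perfect_predictions(self):
        true = ["B", "B", "T", "T"]
        f1, median = per_type_f1(true, true)
        assert f1 == {"B": 1.0, "T": 1.0} and median == 1.0

    def test_never_predicted_type_scores_zero(self):
        f1, _ = per_type_f1(["B", "T"], ["B", "B"])
        assert f1["T"] == 0.0

    def test_matches_hand_confusion_matrix(self):
        # 2 types, 10 cells each; 8/10 and 6/10 correct, symmetric confusion
        true = ["A"] * 10 + ["B"] * 10
        called = ["A"] * 8 + ["B"] * 2 + ["B"] * 6 + ["A"] * 4
        f1, median = per_type_f1(true, called)
        # A: TP=8 FP=4 FN=2 -> P=8/12 R=8/10 F1=2*(2/3)(4/5)/(2/3+4/5)
        pa, ra = 8 / 12, 8 / 10
        pb, rb = 6 / 8, 6 / 10
        assert f1["A"] == pytest.approx(2 * pa * ra / (pa + ra))
        assert f1["B"] == pytest.approx(2 * pb * rb / (pb + rb))
        assert median == pytest.approx(np.median([f1["A"], f1["B"]]))

    def test_unassigned_is_a_miss_never_a_type(self):
        true = ["B", "B", "T"]
        called = [UNASSIGNED, "B", "T"]
        f1, _ = per_type_f1(true, called)
        assert set(f1) == {"B", "T"}
        assert f1["B"] == pytest.approx(2 * (1.0 * 0.5) / 1.5)  # P=1, R=1/2

    def test_invariant_to_permutation(self):
        rng = np.random.default_rng(0)
        true = list(rng.choice(["A", "B", "C"], 30))
        called = list(rng.choice(["A", "B", "C", UNASSIGNED], 30))
        perm = rng.permutation(30)
        a = per_type_f1(true, called)
        b = per_type_f1(np.array(true)[perm], np.array(called)[perm])
        assert a == b


class TestClusterAccuracy:
    def test_all_correct(self):
        truth = pd.Series({"0": "B", "1": "T"})
        assert cluster_accuracy(truth, _calls({"0": "B", "1": "T"})) == 1.0

    def test_three_of_four(self):
        truth = pd.Series({"0": "B", "1": "T", "2": "NK", "3": "Mk"})
        calls = _calls({"0": "B", "1": "T", "2": "NK", "3": "B"})
        assert cluster_accuracy(truth, calls) == 0.75

    def test_strict_rejection_credits_unassigned_for_missing_type(self):
        truth = pd.Series({"0": "B", "1": "Mk"})
        calls = _calls({"0": "B", "1": UNASSIGNED})
        assert (
            cluster_accuracy(truth, calls, reference_types=["B", "T"], strict_rejection=True)
            == 1.0
        )
        # without strict rejection the unassigned cluster counts as a miss
        assert cluster_accuracy(truth, calls) == 0.5

    def test_mismatched_cluster_sets_error(self):
        truth = pd.Series({"0": "B"})
        with pytest.raises(ValueError, match="differ"):
            cluster_accuracy(truth, _calls({"1": "B"}))


class TestOverclusterTest:
    @pytest.fixture(scope="class")
    def separable(self):
        query, meta, ref, _ = generate_dataset(
            SyntheticSpec(n_types=2, cells_per_type=60, n_genes=500,
                          n_signature_genes_per_type=15, seed=3)
        )
        genes = select_top_variance_genes(query, 60)
        # PCA-like reduced coordinates from the variable genes
        sub = query.values.loc[genes].to_numpy().T
        sub = sub - sub.mean(axis=0)
        u, s, _ = np.linalg.svd(sub, full_matrices=False)
        reduced = pd.DataFrame(u[:, :10] * s[:10], index=query.cell_ids)
        return query, meta, ref, genes, reduced

    def test_k2_recovers_both_types(self, separable):
        query, meta, ref, genes, reduced = separable
        calls = overcluster_test(query, reduced, [2], ref, genes, seed=0)[2]
        assert sorted(calls.called_types) == ["type0", "type1"]

    def test_overclustered_subclusters_keep_parent_type(self, separable):
        query, meta, ref, genes, reduced = separable
        calls = overcluster_test(query, reduced, [8], ref, genes, seed=0)[8]
        km_meta_types = meta.clusters  # truth per cell
        from sklearn.cluster import KMeans

        labels = KMeans(n_clusters=8, n_init=10, random_state=0).fit_predict(
            reduced.to_numpy()
        )
        for sub in range(8):
            cells = np.array(query.cell_ids)[labels == sub]
            majority = km_meta_types.loc[cells].mode().iloc[0]
            assert calls.call_for(str(sub)) == majority

    def test_same_seed_reproduces_calls(self, separable):
        query, meta, ref, genes, reduced = separable
        a = overcluster_test(query, reduced, [2, 4], ref, genes, seed=9)
        b = overcluster_test(query, reduced, [2, 4], ref, genes, seed=9)
        for k in (2, 4):
            pd.testing.assert_frame_equal(a[k].table, b[k].table)

    def test_k_not_smaller_than_cells_errors(self, separable):
        query, meta, ref, genes, reduced = separable
        with pytest.raises(ValueError, match="smaller than the number of cells"):
            overcluster_test(query, reduced, [query.n_cells], ref, genes)


class TestBenchmarkCalls:
    def test_synthetic_fixture_scores_perfectly(self, default_dataset):
        query, meta, ref, _ = default_dataset
        genes = select_top_variance_genes(query, 100)
        calls = cor_to_call(clustify(query, meta, ref, genes), threshold=0.5)
        result = benchmark_calls(meta, calls)
        assert result.accuracy == 1.0
        assert result.median_f1 == 1.0
        assert result.median_f1 == np.median(list(result.per_type_f1.values()))
        assert all(v == 0.0 for v in result.rejection_rate.values())

    def test_leave_one_type_out_is_rejected_and_counted(self, default_dataset):
        query, meta, ref, _ = default_dataset
        genes = select_top_variance_genes(query, 100)
        loo = ReferenceMatrix(ref.values.drop(columns="type0"), is_log=ref.is_log)
        calls = cor_to_call(clustify(query, meta, loo, genes), threshold=0.5)
        assert calls.call_for("type0") == UNASSIGNED
        result = benchmark_calls(
            meta, calls, reference_types=loo.type_labels, strict_rejection=True
        )
        assert result.rejection_rate["type0"] == 1.0
        assert result.accuracy == 1.0  # rejection of the held-out type is correct
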