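"""Quality checks and benchmarking metrics.

Covers three practical questions: is a cluster big enough to classify at all
(pseudobulk averages of fewer than ~10 cells are noisy); are calls stable
when the data are intentionally overclustered; and how good are calls against
known labels (per-type F1, median F1, cluster-level accuracy, rejection
rates).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import precision_recall_fscore_support

from .calling import DEFAULT_THRESHOLD, cor_to_call
from .containers import (
    UNASSIGNED,
    CallTable,
    ClusterMetadata,
    ExpressionMatrix,
    ReferenceMatrix,
)
from .correlate import clustify

DEFAULT_MIN_CELLS = 10


def filter_small_clusters(
    meta: ClusterMetadata,
    min_cells: int = DEFAULT_MIN_CELLS,
    strict: bool = False,
) -> tuple[list[str], list[str]]:
    """Flag clusters with fewer than ``min_cells`` cells.

    Default behaviour warns and retains the small clusters; with
    ``strict=True`` they are dropped from the returned kept list so they are
    excluded from classification.

    Returns
    -------
    (kept, messages)
        Sorted cluster labels to classify, and one warning message per
        undersized cluster (also emitted as UserWarning).
    """
    if min_cells < 1:
        raise ValueError("min_cells must be >= 1")
    sizes = meta.cluster_sizes()
    small = sizes.index[sizes < min_cells].tolist()
    messages = [
        f"cluster {label!r} has only {sizes[label]} cells (< {min_cells}); "
        "its average profile may be unreliable"
        for label in small
    ]
    for msg in messages:
        warnings.warn(msg, UserWarning, stacklevel=2)
    kept = sorted(sizes.index.difference(small)) if strict else sorted(sizes.index)
    return list(kept), messages


def overcluster_test(
    query: ExpressionMatrix,
    reduced: pd.DataFrame,
    k_values: list[int],
    ref: ReferenceMatrix,
    query_genes: list[str] | None = None,
    seed: int = 0,
    method: str = "spearman",
    threshold: float | str = DEFAULT_THRESHOLD,
) -> dict[int, CallTable]:
    """Intentionally overcluster and classify, for stability inspection.

    For each k, the cells are k-means clustered (fixed ``seed``, 10 restarts)
    on caller-supplied reduced coordinates (``reduced``: cells x dims, rows
    aligned with ``query`` cells — typically PCA from the upstream pipeline),
    the resulting clusters are classified against ``ref``, and the per-k call
    tables are returned.  Stable annotations keep their parent type as k
    grows.
    """
    reduced = pd.DataFrame(reduced)
    if list(reduced.index) != query.cell_ids:
        if set(reduced.index) != set(query.cell_ids):
            raise ValueError("reduced coordinates must be indexed by the query cell IDs")
        reduced = reduced.loc[query.cell_ids]
    results: dict[int, CallTable] = {}
    for k in k_values:
        if k < 2:
            raise ValueError("each k must be >= 2")
        if k >= query.n_cells:
            raise ValueError(f"k={k} must be smaller than the number of cells ({query.n_cells})")
        km = KMeans(n_clusters=k, n_init=10, random_state=seed)
        labels = km.fit_predict(reduced.to_numpy())
        meta = ClusterMetadata(
            pd.DataFrame({"cluster": labels.astype(str)}, index=query.cell_ids)
        )
        cor = clustify(query, meta, ref, query_genes=query_genes, method=method)
        results[k] = cor_to_call(cor, threshold=threshold)
    return results


def per_type_f1(true_types, called_types) -> tuple[dict[str, float], float]:
    """Per-cell-type F1 scores and their median.

    F1 is the harmonic mean of precision and recall, computed per *true* type.
    ``"unassigned"`` predictions count against their true type's recall but
    are never themselves treated as a predicted type, so rejection always
    costs recall and never earns precision.
    """
    true = pd.Series(true_types).astype(str).to_numpy()
    called = pd.Series(called_types).astype(str).to_numpy()
    if true.shape != called.shape or true.size == 0:
        raise ValueError("true and called labels must be nonempty and of equal length")
    labels = sorted(set(true) - {UNASSIGNED})
    _, _, f1, _ = precision_recall_fscore_support(
        true, called, labels=labels, zero_division=0
    )
    mapping = {lab: float(v) for lab, v in zip(labels, f1)}
    return mapping, float(np.median(list(mapping.values())))


def cluster_accuracy(
    true_cluster_types: pd.Series,
    calls: CallTable,
    reference_types: list[str] | None = None,
    strict_rejection: bool = False,
) -> float:
    """Fraction of clusters whose call matches the true type.

    ``"unassigned"`` counts as incorrect, except under ``strict_rejection``
    when the true type is absent from ``reference_types`` — rejecting a type
    the reference cannot name is then the correct behaviour.
    """
    truth = pd.Series(true_cluster_types).astype(str)
    if set(truth.index) != set(calls.cluster_labels):
        raise ValueError(
            f"cluster sets differ: truth has {sorted(set(truth.index))[:5]}..., "
            f"calls have {sorted(set(calls.cluster_labels))[:5]}..."
        )
    correct = 0
    for cluster, true_type in truth.items():
        called = calls.call_for(cluster)
        if called == true_type:
            correct += 1
        elif (
            called == UNASSIGNED
            and strict_rejection
            and reference_types is not None
            and true_type not in reference_types
        ):
            correct += 1
    return correct / len(truth)


@dataclass
class BenchmarkResult:
    """Summary metrics of a classification run against known labels."""

    per_type_f1: dict[str, float]
    median_f1: float
    accuracy: float
    rejection_rate: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "per_type_f1": self.per_type_f1,
            "median_f1": self.median_f1,
            "accuracy": self.accuracy,
            "rejection_rate": self.rejection_rate,
        }


def benchmark_calls(
    meta: ClusterMetadata,
    calls: CallTable,
    reference_types: list[str] | None = None,
    strict_rejection: bool = False,
) -> BenchmarkResult:
    """Score a call table against the metadata's ``true_type`` column.

    Combines per-cell F1 (cells inherit their cluster's call), cluster-level
    accuracy (majority true type per cluster defines the truth), and the
    per-type fraction of cells left unassigned.
    """
    truth = meta.true_types
    if truth is None:
        raise ValueError("metadata carries no true_type column to benchmark against")
    per_cell_called = meta.clusters.map(calls.table["type"])
    f1_map, median_f1 = per_type_f1(truth, per_cell_called)

    cluster_truth = (
        pd.DataFrame({"cluster": meta.clusters, "true": truth})
        .groupby("cluster")["true"]
        .agg(lambda s: s.mode().iloc[0])
    )
    acc = cluster_accuracy(cluster_truth, calls, reference_types, strict_rejection)

    rejection = {
        t: float((per_cell_called[truth == t] == UNASSIGNED).mean())
        for t in sorted(truth.unique())
    }
    return BenchmarkResult(f1_map, median_f1, acc, rejection)
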