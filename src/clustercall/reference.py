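"""Build reference profile matrices from labelled single-cell data.

The central operation is per-cluster averaging ("pseudobulk"): collapsing the
cells of each cluster into one expression profile that can stand in for a bulk
measurement of that cell type.  When the input is on the log1p scale the mean
is taken in linear space (expm1 -> mean -> log1p) so the profile matches what
a bulk assay of the pooled cells would report; averaging log values directly
is available by passing ``if_log=False`` semantics explicitly on linear data.

``subcluster_reference`` optionally splits each cluster into n**x k-means
subclusters before averaging, emitting several profiles per type to capture
within-type heterogeneity.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .containers import ClusterMetadata, ExpressionMatrix, ReferenceMatrix

#: Gene subspace size used for the subclustering k-means.
SUBCLUSTER_N_GENES = 1000


def _mean_profile(values: pd.DataFrame, if_log: bool) -> pd.Series:
    """Average columns of ``values``; in linear space when ``if_log``."""
    if if_log:
        return np.log1p(np.expm1(values).mean(axis=1))
    return values.mean(axis=1)


def average_clusters(
    mat: ExpressionMatrix,
    meta: ClusterMetadata,
    if_log: bool | None = None,
) -> ReferenceMatrix:
    """Average per-cell expression within each cluster.

    Parameters
    ----------
    mat
        Query expression matrix (genes x cells).
    meta
        Per-cell cluster assignments covering exactly the cells of ``mat``.
    if_log
        When True (default: ``mat.is_log``), undo the log1p transform before
        averaging and re-apply it afterwards, so the profile is a linear-space
        mean reported on the log scale.

    Returns
    -------
    ReferenceMatrix
        One column per distinct cluster label, columns sorted
        lexicographically; gene order is preserved from ``mat``.
    """
    if if_log is None:
        if_log = mat.is_log
    meta.check_covers(mat)
    out = {}
    for label in sorted(meta.clusters.unique()):
        cells = meta.cells_of(label)
        out[label] = _mean_profile(mat.values[cells], if_log)
    frame = pd.DataFrame(out, index=mat.values.index)
    return ReferenceMatrix(frame, is_log=mat.is_log)


def _top_variance_gene_ids(values: pd.DataFrame, n: int) -> list[str]:
    """Gene IDs with largest across-column variance; ties break by gene ID."""
    var = values.var(axis=1, ddof=1).fillna(0.0)
    order = sorted(values.index, key=lambda g: (-var[g], g))
    return order[: min(n, len(order))]


def select_top_variance_genes(
    data: ReferenceMatrix | ExpressionMatrix, n: int = 1000
) -> list[str]:
    """Pick the ``n`` genes with highest variance across columns.

    On a :class:`ReferenceMatrix` this ranks genes by across-type variance; on
    an :class:`ExpressionMatrix` by across-cell variance (a simple
    highly-variable-gene selection for the query).  This is the fallback
    feature selection when no externally computed variable-gene list is
    supplied.  Deterministic: ties are broken by lexicographic gene ID.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    return _top_variance_gene_ids(data.values, n)


def subcluster_reference(
    mat: ExpressionMatrix,
    meta: ClusterMetadata,
    power_x: float,
    seed: int = 0,
    if_log: bool | None = None,
) -> ReferenceMatrix:
    """Average clusters after splitting each into ``n**power_x`` subclusters.

    For a cluster of n cells, s = max(1, floor(n**power_x)) subcluster
    profiles are produced by k-means (k = s, k-means++ init, 10 restarts,
    fixed ``seed``) on that cluster's cells over the matrix-wide top-variance
    genes, then each subcluster is averaged.  Columns are named
    ``"<cluster>_<i>"`` when s > 1 and keep the bare cluster name when s == 1,
    so ``power_x == 0`` reproduces :func:`average_clusters` exactly.
    """
    if not 0 <= power_x <= 1:
        raise ValueError("power_x must lie in [0, 1]")
    if if_log is None:
        if_log = mat.is_log
    meta.check_covers(mat)
    top_genes = _top_variance_gene_ids(mat.values, SUBCLUSTER_N_GENES)
    columns: dict[str, pd.Series] = {}
    for label in sorted(meta.clusters.unique()):
        cells = meta.cells_of(label)
        n = len(cells)
        s = max(1, int(np.floor(n ** power_x)))
        if s <= 1 or n == 1:
            columns[label] = _mean_profile(mat.values[cells], if_log)
            continue
        coords = mat.values.loc[top_genes, cells].to_numpy().T  # cells x genes
        km = KMeans(n_clusters=s, init="k-means++", n_init=10, random_state=seed)
        assignment = km.fit_predict(coords)
        for i in range(s):
            sub_cells = [c for c, a in zip(cells, assignment) if a == i]
            if not sub_cells:  # k-means can leave a centroid empty only pathologically
                continue
            columns[f"{label}_{i + 1}"] = _mean_profile(mat.values[sub_cells], if_log)
    frame = pd.DataFrame(columns, index=mat.values.index)
    return ReferenceMatrix(frame, is_log=mat.is_log)
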