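"""Correlation of query cluster profiles against reference transcriptomes.

The classifier is deliberately simple: average each query cluster to a
pseudobulk profile, restrict query and reference to a shared variable-gene
set, and fill a clusters x types matrix of similarity coefficients.  Spearman
rank correlation is the default because it is insensitive to the (usually
different) normalization scales of query and reference data; Pearson, Kendall
tau-b and uncentered cosine similarity are available alternatives.

Zero-variance profiles (or zero-norm, for cosine) yield NaN coefficients
rather than errors; the calling step treats NaN as "never the winner".
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ClusterMetadata, CorrelationMatrix, ExpressionMatrix, ReferenceMatrix
from .reference import average_clusters

logger = logging.getLogger(__name__)

METHODS = ("spearman", "pearson", "kendall", "cosine")

#: Below this many usable genes the coefficient estimates get noisy enough
#: that a UserWarning is raised in addition to the logged intersection size.
MIN_COMFORTABLE_GENES = 100


def _rank_columns(a: np.ndarray) -> np.ndarray:
    """Average (fractional) ranks down each column."""
    return np.apply_along_axis(stats.rankdata, 0, a)


def _pearson_cross(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pearson correlation between every column of ``a`` and of ``b``.

    Columns with zero variance produce NaN rows/columns.
    """
    ac = a - a.mean(axis=0)
    bc = b - b.mean(axis=0)
    na = np.linalg.norm(ac, axis=0)
    nb = np.linalg.norm(bc, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (ac.T @ bc) / np.outer(na, nb)
    r[na == 0, :] = np.nan
    r[:, nb == 0] = np.nan
    return np.clip(r, -1.0, 1.0, out=r)


def _cosine_cross(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    na = np.linalg.norm(a, axis=0)
    nb = np.linalg.norm(b, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (a.T @ b) / np.outer(na, nb)
    r[na == 0, :] = np.nan
    r[:, nb == 0] = np.nan
    return np.clip(r, -1.0, 1.0, out=r)


def _cross_correlate(a: np.ndarray, b: np.ndarray, method: str) -> np.ndarray:
    """Coefficients between all column pairs of ``a`` (n x p) and ``b`` (n x q)."""
    if method == "pearson":
        return _pearson_cross(a, b)
    if method == "spearman":
        return _pearson_cross(_rank_columns(a), _rank_columns(b))
    if method == "cosine":
        return _cosine_cross(a, b)
    if method == "kendall":
        out = np.empty((a.shape[1], b.shape[1]))
        for i in range(a.shape[1]):
            for j in range(b.shape[1]):
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    out[i, j] = stats.kendalltau(a[:, i], b[:, j]).statistic
        return out
    raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")


def correlate_vectors(x, y, method: str = "spearman") -> float:
    """Similarity coefficient between two expression vectors.

    spearman
        Pearson correlation of average-tie ranks.
    pearson
        Ordinary product-moment correlation.
    kendall
        Tau-b, tie-corrected.
    cosine
        Uncentered cosine similarity on the raw values.

    Returns NaN when either vector has zero variance (zero norm for cosine).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError(f"vectors must be 1-D of equal length, got {x.shape} vs {y.shape}")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    return float(_cross_correlate(x[:, None], y[:, None], method)[0, 0])


def clustify(
    query: ExpressionMatrix,
    meta: ClusterMetadata | None,
    ref: ReferenceMatrix,
    query_genes: list[str] | None = None,
    method: str = "spearman",
    per_cell: bool = False,
) -> CorrelationMatrix:
    """Correlate query cluster averages with reference cell-type profiles.

    Parameters
    ----------
    query
        Normalized expression, genes x cells.
    meta
        Cluster assignments; may be None only in ``per_cell`` mode.
    ref
        Reference profiles, genes x types.
    query_genes
        Variable-gene list over which to correlate (e.g. an externally
        computed set, or :func:`~clustercall.reference.select_top_variance_genes`).
        None means all genes shared by query and reference.  Genes absent from
        either side are dropped silently; the usable intersection size is
        logged, with a UserWarning below 100 genes.
    method
        One of spearman / pearson / kendall / cosine.
    per_cell
        Correlate individual cells instead of cluster averages.  Accuracy
        degrades with per-cell profiles; cluster mode is recommended.

    Returns
    -------
    CorrelationMatrix
        Rows are query clusters (or cells in ``per_cell`` mode), columns
        reference types.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
    if per_cell:
        profiles = query.values
    else:
        if meta is None:
            raise ValueError("cluster metadata is required unless per_cell=True")
        profiles = average_clusters(query, meta, if_log=query.is_log).values

    if query_genes is None:
        genes = [g for g in query.gene_ids if g in set(ref.gene_ids)]
    else:
        seen: set[str] = set()
        ordered = [g for g in query_genes if not (g in seen or seen.add(g))]
        in_query = set(query.gene_ids)
        in_ref = set(ref.gene_ids)
        genes = [g for g in ordered if g in in_query and g in in_ref]
    if not genes:
        raise ValueError("no usable genes: the query/reference/gene-list intersection is empty")
    logger.info("correlating over %d usable genes (%s)", len(genes), method)
    if len(genes) < MIN_COMFORTABLE_GENES:
        warnings.warn(
            f"only {len(genes)} usable genes after intersecting query, reference "
            "and gene list; coefficients may be unstable",
            UserWarning,
            stacklevel=2,
        )

    a = profiles.loc[genes].to_numpy(dtype=float)
    b = ref.values.loc[genes].to_numpy(dtype=float)
    vals = _cross_correlate(a, b, method)
    frame = pd.DataFrame(vals, index=profiles.columns, columns=ref.values.columns)
    return CorrelationMatrix(frame, method=method)
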