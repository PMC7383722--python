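"""Gene-list based cluster classification.

Instead of correlating full expression profiles, a query cluster can be
matched to reference cell types through marker-gene lists: hypergeometric
overlap enrichment, the Jaccard index, the fraction of marker genes detected
in the cluster, or a permutation GSEA on a per-cluster gene ranking.  These
are useful when the reference exists only as curated marker lists rather than
as transcriptome profiles.

Scores are oriented so that larger is always better (hypergeometric p-values
are reported as -log10 p), and the same argmax-plus-threshold calling used
for correlations applies.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .calling import scores_to_call
from .containers import CallTable, ClusterMetadata, ExpressionMatrix, MarkerTable
from .reference import average_clusters

LIST_METRICS = ("hypergeom", "jaccard", "pct", "gsea")

#: Default calling cutoffs per metric, on the reported (larger-better) scale.
DEFAULT_LIST_THRESHOLDS = {"hypergeom": 5.0, "jaccard": 0.0, "pct": 0.0, "gsea": 0.0}

_MAX_NEGLOG10 = 320.0  # cap so -log10(p) stays finite at p == 0 in float64


def hypergeom_enrich(query_set, ref_set, universe_n: int) -> float:
    """Upper-tail hypergeometric probability of the observed marker overlap.

    Draws |query_set| genes from a universe of ``universe_n`` containing
    |ref_set| successes and returns P(X >= k) for the observed overlap k,
    by exact summation of the tail probability mass.
    """
    a = set(query_set)
    b = set(ref_set)
    if universe_n < len(a | b):
        raise ValueError(
            f"universe ({universe_n}) smaller than the union of the sets ({len(a | b)})"
        )
    k = len(a & b)
    upper = min(len(a), len(b))
    if k == 0:
        return 1.0
    support = np.arange(k, upper + 1)
    p = float(stats.hypergeom.pmf(support, universe_n, len(b), len(a)).sum())
    return min(p, 1.0)


def jaccard(set_a, set_b) -> float:
    """|A n B| / |A u B|; defined as 0 (with a warning) when both are empty."""
    a, b = set(set_a), set(set_b)
    union = a | b
    if not union:
        warnings.warn("jaccard of two empty sets; returning 0", UserWarning, stacklevel=2)
        return 0.0
    return len(a & b) / len(union)


def pct_detection(
    mat: ExpressionMatrix,
    meta: ClusterMetadata,
    gene_list,
) -> pd.Series:
    """Per-cluster mean detection rate of a gene list.

    For each cluster: the mean over listed genes of the fraction of that
    cluster's cells with expression > 0.
    """
    genes = [g for g in dict.fromkeys(gene_list) if g in set(mat.gene_ids)]
    if not genes:
        raise ValueError("none of the listed genes are present in the matrix")
    meta.check_covers(mat)
    detected = mat.values.loc[genes] > 0
    out = {}
    for label in sorted(meta.clusters.unique()):
        cells = meta.cells_of(label)
        out[label] = float(detected[cells].mean(axis=1).mean())
    return pd.Series(out, name="pct_detection")


def gsea_running_sum(
    ranked_scores: pd.Series,
    gene_set,
    weight_exponent: float = 1.0,
) -> tuple[float, np.ndarray]:
    """Weighted Kolmogorov-Smirnov running sum for one ranked list.

    ``ranked_scores`` must be ordered best-first (descending score).  Hits
    contribute |score|**weight_exponent normalized over in-set weight; misses
    decrement by 1/(N - Nh).  Returns the signed enrichment score (the running
    sum's maximum deviation from zero) and the full running sum.
    """
    hits = ranked_scores.index.isin(set(gene_set))
    n = len(ranked_scores)
    n_hit = int(hits.sum())
    if n_hit == 0 or n_hit == n:
        raise ValueError("gene set must hit a strict, nonempty subset of the ranking")
    w = np.abs(ranked_scores.to_numpy(dtype=float)) ** weight_exponent
    hit_w = np.where(hits, w, 0.0)
    total_hit_w = hit_w.sum()
    if total_hit_w == 0:  # all in-set scores exactly 0: fall back to unweighted
        hit_w = hits.astype(float)
        total_hit_w = hit_w.sum()
    step = hit_w / total_hit_w - (~hits).astype(float) / (n - n_hit)
    running = np.cumsum(step)
    es = float(running[np.argmax(np.abs(running))])
    return es, running


def gsea_score(
    ranked_scores: pd.Series,
    gene_set,
    n_perm: int = 1000,
    seed: int = 0,
    weight_exponent: float = 1.0,
) -> tuple[float, float]:
    """Classic permutation GSEA: enrichment score and gene-permutation p-value.

    Parameters
    ----------
    ranked_scores
        Gene-indexed scores; sorted internally by descending score (ties break
        by gene ID for determinism).
    gene_set
        Genes whose concentration near the top of the ranking is tested; must
        intersect the ranking.
    n_perm
        Number of random same-size gene sets drawn for the null (>= 100).
    seed
        Seed for the permutation draws; results are deterministic given it.

    Returns
    -------
    (es, p)
        Signed enrichment score and the one-sided permutation p-value for the
        observed sign, with the +1 pseudo-count correction.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    order = sorted(ranked_scores.index, key=lambda g: (-ranked_scores[g], g))
    ranked = ranked_scores.loc[order]
    in_set = [g for g in ranked.index if g in set(gene_set)]
    if not in_set:
        raise ValueError("gene set does not intersect the ranked list")
    es, _ = gsea_running_sum(ranked, in_set, weight_exponent)

    rng = np.random.default_rng(seed)
    n, n_hit = len(ranked), len(in_set)
    w = np.abs(ranked.to_numpy(dtype=float)) ** weight_exponent
    exceed = 0
    for _ in range(n_perm):
        idx = rng.choice(n, size=n_hit, replace=False)
        hits = np.zeros(n, dtype=bool)
        hits[idx] = True
        hit_w = np.where(hits, w, 0.0)
        tot = hit_w.sum()
        if tot == 0:
            hit_w = hits.astype(float)
            tot = float(n_hit)
        step = hit_w / tot - (~hits).astype(float) / (n - n_hit)
        running = np.cumsum(step)
        es_p = running[np.argmax(np.abs(running))]
        if (es >= 0 and es_p >= es) or (es < 0 and es_p <= es):
            exceed += 1
    p = (exceed + 1) / (n_perm + 1)
    return es, float(p)


def rank_cluster_markers(
    mat: ExpressionMatrix,
    meta: ClusterMetadata,
    n_markers: int = 100,
) -> MarkerTable:
    """Derive per-cluster marker lists from expression.

    Genes are ranked per cluster by the difference between the cluster's mean
    expression and the mean over all other cells (a simple log-fold-change
    surrogate); the top ``n_markers`` become that cluster's markers.
    """
    meta.check_covers(mat)
    profiles = average_clusters(mat, meta, if_log=mat.is_log).values
    lists = {}
    for label in profiles.columns:
        others = [c for c in profiles.columns if c != label]
        delta = profiles[label] - (profiles[others].mean(axis=1) if others else 0.0)
        order = sorted(delta.index, key=lambda g: (-delta[g], g))
        lists[label] = order[: min(n_markers, len(order))]
    return MarkerTable(lists)


def cluster_gene_rankings(mat: ExpressionMatrix, meta: ClusterMetadata) -> dict[str, pd.Series]:
    """Per-cluster gene scores (cluster mean minus rest mean), for GSEA."""
    meta.check_covers(mat)
    profiles = average_clusters(mat, meta, if_log=mat.is_log).values
    out = {}
    for label in profiles.columns:
        others = [c for c in profiles.columns if c != label]
        delta = profiles[label] - (profiles[others].mean(axis=1) if others else 0.0)
        out[label] = delta
    return out


def clustify_lists(
    query_markers: MarkerTable,
    ref_markers: MarkerTable,
    metric: str = "hypergeom",
    universe_n: int | None = None,
    mat: ExpressionMatrix | None = None,
    meta: ClusterMetadata | None = None,
    threshold: float | None = None,
    n_perm: int = 1000,
    seed: int = 0,
) -> tuple[pd.DataFrame, CallTable]:
    """Score query clusters against reference marker lists and call types.

    Parameters
    ----------
    query_markers
        Marker lists keyed by query cluster (see :func:`rank_cluster_markers`).
    ref_markers
        Marker lists keyed by reference cell type.
    metric
        ``hypergeom`` (scored as -log10 p), ``jaccard``, ``pct`` (mean marker
        detection rate per cluster; needs ``mat``/``meta``) or ``gsea``
        (enrichment score on the per-cluster gene ranking; needs ``mat``/
        ``meta``).
    universe_n
        Hypergeometric universe size; defaults to the matrix gene count union
        with all reference markers when ``mat`` is given, else the union of
        all marker genes on both sides.
    threshold
        Calling cutoff on the reported score scale; metric-specific default.

    Returns
    -------
    (scores, calls)
        Clusters x types score matrix (larger = better) and its CallTable.
    """
    if metric not in LIST_METRICS:
        raise ValueError(f"unknown metric {metric!r}; expected one of {LIST_METRICS}")
    if not query_markers.lists or not ref_markers.lists:
        raise ValueError("marker tables must be nonempty")
    if threshold is None:
        threshold = DEFAULT_LIST_THRESHOLDS[metric]

    clusters = query_markers.types
    types = ref_markers.types
    scores = pd.DataFrame(np.nan, index=clusters, columns=types, dtype=float)

    if metric == "hypergeom":
        if universe_n is None:
            if mat is not None:
                universe_n = len(set(mat.gene_ids) | ref_markers.all_genes())
            else:
                universe_n = len(query_markers.all_genes() | ref_markers.all_genes())
        for c in clusters:
            for t in types:
                p = hypergeom_enrich(query_markers[c], ref_markers[t], universe_n)
                scores.loc[c, t] = min(-np.log10(p), _MAX_NEGLOG10) if p > 0 else _MAX_NEGLOG10
    elif metric == "jaccard":
        for c in clusters:
            for t in types:
                scores.loc[c, t] = jaccard(query_markers[c], ref_markers[t])
    elif metric == "pct":
        if mat is None or meta is None:
            raise ValueError("metric 'pct' needs the expression matrix and metadata")
        for t in types:
            per_cluster = pct_detection(mat, meta, ref_markers[t])
            for c in clusters:
                if c in per_cluster.index:
                    scores.loc[c, t] = per_cluster[c]
    else:  # gsea
        if mat is None or meta is None:
            raise ValueError("metric 'gsea' needs the expression matrix and metadata")
        rankings = cluster_gene_rankings(mat, meta)
        for c in clusters:
            delta = rankings[c]
            order = sorted(delta.index, key=lambda g: (-delta[g], g))
            ranking = delta.loc[order]
            for t in types:
                present = [g for g in ref_markers[t] if g in set(ranking.index)]
                if not present or len(present) == len(ranking):
                    continue
                es, _ = gsea_running_sum(ranking, present)
                scores.loc[c, t] = es

    return scores, scores_to_call(scores, threshold)
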