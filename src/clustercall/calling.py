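"""Turn score matrices into per-cluster cell-type calls.

A cluster is assigned the best-scoring reference type unless that score falls
below a cutoff, in which case it is labelled ``"unassigned"`` — the mechanism
by which cell types missing from the reference are rejected rather than
mislabelled.  The cutoff is either a fixed number (0.5 and 0.4 both work well
for rank correlations in practice) or the heuristic 0.8 x the highest
coefficient observed, applied to the matrix globally by default or per row.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import UNASSIGNED, CallTable, ClusterMetadata, CorrelationMatrix

DEFAULT_THRESHOLD = 0.5
AUTO_FACTOR = 0.8


def scores_to_call(scores: pd.DataFrame, threshold) -> CallTable:
    """Argmax calling on an arbitrary clusters x types score matrix.

    ``threshold`` is a scalar or a per-row Series; rows whose winning score is
    below their threshold (or that contain no finite score) become
    ``"unassigned"``.  Ties at the maximum break to the lexicographically
    smallest type label.
    """
    if scores.empty:
        raise ValueError("score matrix is empty")
    if np.isscalar(threshold):
        thr = pd.Series(float(threshold), index=scores.index)
    else:
        thr = pd.Series(threshold).reindex(scores.index)
    rows = []
    for cluster, row in scores.iterrows():
        finite = row[np.isfinite(row.to_numpy(dtype=float))]
        t = float(thr[cluster])
        if finite.empty:
            rows.append((cluster, UNASSIGNED, np.nan, t))
            continue
        best = finite.max()
        winner = min(finite.index[finite == best])  # lexicographic tie-break
        called = winner if best >= t else UNASSIGNED
        rows.append((cluster, called, float(best), t))
    table = pd.DataFrame(rows, columns=["cluster", "type", "score", "threshold"])
    return CallTable(table.set_index("cluster"))


def cor_to_call(
    cor: CorrelationMatrix,
    threshold: float | str = DEFAULT_THRESHOLD,
    auto_scope: str = "global",
) -> CallTable:
    """Call each query cluster from its correlation row.

    Parameters
    ----------
    cor
        Clusters x types correlation matrix.
    threshold
        Numeric cutoff used as-is, or ``"auto"`` for 0.8 x the highest
        coefficient.  With ``auto_scope="global"`` (default) the heuristic
        uses the single highest coefficient in the whole matrix; with
        ``"row"`` each cluster uses 0.8 x its own best coefficient.
    """
    values = cor.values.astype(float)
    if isinstance(threshold, str):
        if threshold != "auto":
            raise ValueError(f"threshold must be numeric or 'auto', got {threshold!r}")
        if auto_scope == "global":
            arr = values.to_numpy()
            finite = arr[np.isfinite(arr)]
            thr = AUTO_FACTOR * float(finite.max()) if finite.size else np.inf
        elif auto_scope == "row":
            thr = AUTO_FACTOR * values.max(axis=1, skipna=True)
        else:
            raise ValueError("auto_scope must be 'global' or 'row'")
    else:
        thr = float(threshold)
    return scores_to_call(values, thr)


def call_consensus(calls: list[CallTable]) -> CallTable:
    """Merge calls from several correlation methods by per-cluster majority.

    The modal called type wins; ties (including 1-1 splits) fall back to
    ``"unassigned"``.  An ``"unassigned"`` call counts as a vote like any
    other.  The reported score is the mean score of the agreeing tables (NaN
    for a tied/unassigned consensus with no agreeing votes).
    """
    if not calls:
        raise ValueError("need at least one call table")
    base = set(calls[0].cluster_labels)
    for ct in calls[1:]:
        if set(ct.cluster_labels) != base:
            raise ValueError("call tables disagree on the cluster set")
    rows = []
    for cluster in calls[0].cluster_labels:
        votes = pd.Series([ct.call_for(cluster) for ct in calls])
        counts = votes.value_counts()
        top = counts[counts == counts.max()]
        if len(top) > 1:
            winner = UNASSIGNED
        else:
            winner = top.index[0]
        agreeing = [
            float(ct.table.loc[cluster, "score"])
            for ct in calls
            if ct.call_for(cluster) == winner
        ]
        score = float(np.nanmean(agreeing)) if agreeing else np.nan
        thr = float(np.nanmean([float(ct.table.loc[cluster, "threshold"]) for ct in calls]))
        rows.append((cluster, winner, score, thr))
    table = pd.DataFrame(rows, columns=["cluster", "type", "score", "threshold"])
    return CallTable(table.set_index("cluster"))


def attach_calls(meta: ClusterMetadata, calls: CallTable) -> pd.DataFrame:
    """Broadcast per-cluster calls back onto the per-cell metadata table.

    Returns a copy of the metadata with added ``type`` and ``r`` columns.
    Every cluster present in the metadata must appear in the call table.
    """
    missing = sorted(set(meta.clusters.unique()) - set(calls.cluster_labels))
    if missing:
        raise KeyError(f"clusters missing from call table: {missing}")
    out = meta.table.copy()
    out["type"] = meta.clusters.map(calls.table["type"]).to_numpy()
    out["r"] = meta.clusters.map(calls.table["score"]).to_numpy()
    return out
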