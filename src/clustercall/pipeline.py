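"""End-to-end orchestration: read -> filter -> classify -> call -> write.

This is the layer the CLI wraps; library users can equally call it directly
with a :class:`RunConfig`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from .calling import DEFAULT_THRESHOLD, attach_calls, cor_to_call
from .containers import CallTable, ClusterMetadata, ExpressionMatrix, ReferenceMatrix
from .correlate import clustify
from .diagnostics import DEFAULT_MIN_CELLS, filter_small_clusters
from .enrichment import clustify_lists, rank_cluster_markers
from .io import (
    read_expression,
    read_gene_list,
    read_marker_table,
    read_metadata,
    read_reference_tsv,
    write_call_table,
    write_correlation_tsv,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Knobs of a classification run.

    ``threshold`` is a numeric cutoff or the string ``"auto"`` (0.8 x the
    highest observed coefficient).  ``metric`` switches the list-based
    classifier; ``n_markers`` controls how many per-cluster markers are
    derived from the query for list metrics.
    """

    method: str = "spearman"
    threshold: float | str = DEFAULT_THRESHOLD
    min_cells: int = DEFAULT_MIN_CELLS
    strict_min_cells: bool = False
    per_cell: bool = False
    metric: str = "hypergeom"
    n_markers: int = 100
    universe_n: int | None = None
    seed: int = 0
    auto_scope: str = "global"

    def __post_init__(self) -> None:
        if isinstance(self.threshold, str):
            if self.threshold != "auto":
                raise ValueError(f"threshold must be numeric or 'auto', got {self.threshold!r}")
        else:
            self.threshold = float(self.threshold)


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise type(exc)(f"[{name}] {exc}") from exc

        return wrapped

    return deco


def classify_expression(
    query: ExpressionMatrix,
    meta: ClusterMetadata,
    ref: ReferenceMatrix,
    query_genes: list[str] | None = None,
    config: RunConfig | None = None,
):
    """Correlation classification on in-memory objects.

    Applies the small-cluster filter, correlates, calls, and broadcasts calls
    back to cells.  Returns ``(cor, calls, per_cell_table)``.
    """
    config = config or RunConfig()
    kept, _ = filter_small_clusters(meta, config.min_cells, strict=config.strict_min_cells)
    if config.strict_min_cells:
        keep_cells = meta.table.index[meta.clusters.isin(kept)].tolist()
        meta = meta.subset(keep_cells)
        query = ExpressionMatrix(query.values[keep_cells], is_log=query.is_log)
    cor = clustify(
        query, meta, ref, query_genes=query_genes, method=config.method,
        per_cell=config.per_cell,
    )
    calls = cor_to_call(cor, threshold=config.threshold, auto_scope=config.auto_scope)
    logger.info(
        "called %d/%d clusters (threshold=%s)",
        int((calls.called_types != "unassigned").sum()),
        len(calls.cluster_labels),
        config.threshold,
    )
    annotated = None if config.per_cell else attach_calls(meta, calls)
    return cor, calls, annotated


def run_pipeline(config: RunConfig, paths: dict) -> CallTable:
    """File-to-file classification run.

    ``paths`` keys: ``query`` (expression matrix), ``metadata``,
    ``cluster_col``, ``ref`` (reference TSV), optional ``genes`` (variable
    gene list), optional ``ref_markers`` (marker table; switches to the list
    classifier), and ``out_prefix``.  Writes ``<prefix>_cor.tsv``,
    ``<prefix>_calls.tsv`` and ``<prefix>_cells.tsv``.
    """
    out_prefix = Path(paths["out_prefix"])
    out_prefix.parent.mkdir(parents=True, exist_ok=True)

    query = _stage("read query")(read_expression)(paths["query"])
    meta = _stage("read metadata")(read_metadata)(
        paths["metadata"], paths["cluster_col"], paths.get("true_type_col")
    )
    logger.info("query: %d genes x %d cells, %d clusters",
                query.n_genes, query.n_cells, meta.clusters.nunique())

    if "ref_markers" in paths:
        ref_markers = _stage("read markers")(read_marker_table)(paths["ref_markers"])
        query_markers = rank_cluster_markers(query, meta, n_markers=config.n_markers)
        scores, calls = _stage("classify-lists")(clustify_lists)(
            query_markers,
            ref_markers,
            metric=config.metric,
            universe_n=config.universe_n,
            mat=query,
            meta=meta,
            # metric-specific default unless an explicit numeric cutoff was given
            threshold=(
                None
                if isinstance(config.threshold, str) or config.threshold == DEFAULT_THRESHOLD
                else float(config.threshold)
            ),
            seed=config.seed,
        )
        write_correlation_tsv(scores, f"{out_prefix}_scores.tsv")
        write_call_table(calls, f"{out_prefix}_calls.tsv")
        annotated = attach_calls(meta, calls)
        annotated.rename_axis("cell").to_csv(f"{out_prefix}_cells.tsv", sep="\t")
        return calls

    ref = _stage("read reference")(read_reference_tsv)(paths["ref"])
    genes = _stage("read gene list")(read_gene_list)(paths["genes"]) if paths.get("genes") else None
    cor, calls, annotated = _stage("classify")(classify_expression)(
        query, meta, ref, genes, config
    )
    write_correlation_tsv(cor.values, f"{out_prefix}_cor.tsv")
    write_call_table(calls, f"{out_prefix}_calls.tsv")
    if annotated is not None:
        annotated.rename_axis("cell").to_csv(f"{out_prefix}_cells.tsv", sep="\t")
    return calls
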