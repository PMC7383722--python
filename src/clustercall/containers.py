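"""Core data containers.

All expression-like matrices are oriented genes x observations and carried as
labelled :class:`pandas.DataFrame` objects (index = gene IDs, columns = cell or
cell-type IDs).  The thin dataclass wrappers below add the invariants the rest
of the package relies on: unique labels, finite values, and an explicit flag
recording whether values are on the log1p scale.

Gene and cell identifiers are matched by exact, case-sensitive string equality
throughout; no symbol/alias mapping is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Sentinel label for query clusters rejected by the calling step.
UNASSIGNED = "unassigned"


def _require_unique(labels: pd.Index, what: str) -> None:
    if labels.has_duplicates:
        dups = labels[labels.duplicated()].unique().tolist()[:5]
        raise ValueError(f"duplicate {what}: {dups}")


def _require_finite(values: np.ndarray, what: str) -> None:
    if not np.isfinite(values).all():
        raise ValueError(f"{what} contains non-finite values")


@dataclass
class ExpressionMatrix:
    """Normalized expression, genes x cells.

    Parameters
    ----------
    values
        DataFrame with gene IDs as index and cell IDs as columns.
    is_log
        True when values are log1p-transformed normalized counts (the usual
        input scale); such values must be non-negative.
    """

    values: pd.DataFrame
    is_log: bool = True

    def __post_init__(self) -> None:
        self.values = pd.DataFrame(self.values).rename_axis(index=None, columns=None)
        _require_unique(self.values.index, "gene IDs")
        _require_unique(self.values.columns, "cell IDs")
        arr = self.values.to_numpy()
        _require_finite(arr, "expression matrix")
        if self.is_log and (arr < 0).any():
            raise ValueError("log1p-scale expression must be non-negative")

    @property
    def gene_ids(self) -> list[str]:
        return self.values.index.tolist()

    @property
    def cell_ids(self) -> list[str]:
        return self.values.columns.tolist()

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]


@dataclass
class ClusterMetadata:
    """Per-cell cluster assignments, with optional known true types.

    ``table`` is indexed by cell ID and holds a ``cluster`` column; a
    ``true_type`` column may be present for benchmarking.
    """

    table: pd.DataFrame

    CLUSTER_COL = "cluster"
    TRUE_TYPE_COL = "true_type"

    def __post_init__(self) -> None:
        self.table = pd.DataFrame(self.table)
        if self.CLUSTER_COL not in self.table.columns:
            raise ValueError(f"metadata must contain a '{self.CLUSTER_COL}' column")
        _require_unique(self.table.index, "cell IDs")
        labels = self.table[self.CLUSTER_COL]
        if labels.isna().any() or (labels.astype(str).str.len() == 0).any():
            bad = self.table.index[labels.isna() | (labels.astype(str).str.len() == 0)]
            raise ValueError(f"empty cluster label for cells: {bad.tolist()[:5]}")
        self.table[self.CLUSTER_COL] = labels.astype(str)

    @classmethod
    def from_frame(
        cls,
        frame: pd.DataFrame,
        cluster_col: str,
        true_type_col: str | None = None,
        cell_id_col: str | None = None,
    ) -> "ClusterMetadata":
        """Build from an arbitrary per-cell table by naming its columns."""
        df = frame.copy()
        if cell_id_col is not None:
            df = df.set_index(cell_id_col)
        if cluster_col not in df.columns:
            raise KeyError(f"cluster column {cluster_col!r} not found in metadata "
                           f"(columns: {df.columns.tolist()})")
        out = pd.DataFrame(index=df.index.astype(str))
        out[cls.CLUSTER_COL] = df[cluster_col].astype(str).to_numpy()
        if true_type_col is not None:
            out[cls.TRUE_TYPE_COL] = df[true_type_col].astype(str).to_numpy()
        return cls(out)

    @property
    def cell_ids(self) -> list[str]:
        return self.table.index.tolist()

    @property
    def clusters(self) -> pd.Series:
        return self.table[self.CLUSTER_COL]

    @property
    def true_types(self) -> pd.Series | None:
        if self.TRUE_TYPE_COL in self.table.columns:
            return self.table[self.TRUE_TYPE_COL]
        return None

    def cluster_sizes(self) -> pd.Series:
        return self.clusters.value_counts().sort_index()

    def cells_of(self, cluster: str) -> list[str]:
        return self.table.index[self.clusters == cluster].tolist()

    def check_covers(self, mat: ExpressionMatrix) -> None:
        """Require metadata cells and matrix cells to coincide as sets."""
        meta_cells = set(self.table.index)
        mat_cells = set(mat.cell_ids)
        missing = sorted(meta_cells - mat_cells)
        if missing:
            raise ValueError(f"cells in metadata absent from matrix: {missing[:10]}")
        uncovered = sorted(mat_cells - meta_cells)
        if uncovered:
            raise ValueError(f"matrix cells missing from metadata: {uncovered[:10]}")

    def subset(self, cells: list[str]) -> "ClusterMetadata":
        return ClusterMetadata(self.table.loc[cells].copy())


@dataclass
class ReferenceMatrix:
    """Per-cell-type expression profiles, genes x types."""

    values: pd.DataFrame
    is_log: bool = True

    def __post_init__(self) -> None:
        self.values = pd.DataFrame(self.values).rename_axis(index=None, columns=None)
        _require_unique(self.values.index, "gene IDs")
        _require_unique(self.values.columns, "type labels")
        _require_finite(self.values.to_numpy(), "reference matrix")

    @property
    def gene_ids(self) -> list[str]:
        return self.values.index.tolist()

    @property
    def type_labels(self) -> list[str]:
        return self.values.columns.tolist()


@dataclass
class CorrelationMatrix:
    """Query clusters x reference types similarity coefficients.

    Undefined coefficients (zero-variance profiles) are stored as NaN; all
    finite entries lie in [-1, 1].
    """

    values: pd.DataFrame
    method: str

    def __post_init__(self) -> None:
        self.values = pd.DataFrame(self.values)
        _require_unique(self.values.index, "cluster labels")
        _require_unique(self.values.columns, "type labels")
        arr = self.values.to_numpy(dtype=float)
        finite = arr[np.isfinite(arr)]
        if finite.size and (np.abs(finite) > 1 + 1e-9).any():
            raise ValueError("correlation coefficients must lie in [-1, 1]")

    @property
    def cluster_labels(self) -> list[str]:
        return self.values.index.tolist()

    @property
    def type_labels(self) -> list[str]:
        return self.values.columns.tolist()


@dataclass
class CallTable:
    """Per-cluster cell-type calls.

    ``table`` is indexed by cluster label with columns ``type`` (the called
    type or :data:`UNASSIGNED`), ``score`` (the winning coefficient, NaN when
    no finite coefficient existed) and ``threshold`` (the cutoff applied to
    that row).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        self.table = pd.DataFrame(self.table)
        for col in ("type", "score", "threshold"):
            if col not in self.table.columns:
                raise ValueError(f"call table missing column {col!r}")
        _require_unique(self.table.index, "cluster labels")

    @property
    def cluster_labels(self) -> list[str]:
        return self.table.index.tolist()

    @property
    def called_types(self) -> pd.Series:
        return self.table["type"]

    def call_for(self, cluster: str) -> str:
        return str(self.table.loc[cluster, "type"])


@dataclass
class MarkerTable:
    """Ordered marker-gene lists keyed by cell type (or query cluster)."""

    lists: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.lists.items():
            genes = [str(g) for g in genes]
            if len(set(genes)) != len(genes):
                raise ValueError(f"duplicate marker genes in list {name!r}")
            self.lists[name] = genes

    @property
    def types(self) -> list[str]:
        return list(self.lists)

    def __getitem__(self, name: str) -> list[str]:
        return self.lists[name]

    def all_genes(self) -> set[str]:
        out: set[str] = set()
        for genes in self.lists.values():
            out.update(genes)
        return out
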