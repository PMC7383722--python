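"""Readers and writers for the standard on-disk formats.

Everything is normalized to the package's genes x cells orientation on read:
MatrixMarket triplets are assumed genes-in-rows with ``features.tsv`` /
``barcodes.tsv`` sidecars (the common CellRanger-style layout), dense CSV/TSV
has genes in rows with a cell-ID header, and H5AD is transposed from its
cells x genes convention.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .containers import CallTable, ClusterMetadata, ExpressionMatrix, MarkerTable, ReferenceMatrix

logger = logging.getLogger(__name__)


def _dedup_genes(values: pd.DataFrame) -> pd.DataFrame:
    # keep the highest-mean row among duplicates of a gene ID
    if not values.index.has_duplicates:
        return values
    dups = values.index[values.index.duplicated()].unique().tolist()
    logger.warning("de-duplicating %d duplicate gene IDs (keeping highest-mean row)", len(dups))
    means = values.mean(axis=1)
    order = np.argsort(-means.to_numpy(), kind="stable")
    deduped = values.iloc[order][~values.index[order].duplicated()]
    return deduped.loc[[g for g in dict.fromkeys(values.index) if g in deduped.index]]


def _infer_format(path: Path) -> str:
    if path.is_dir() or path.suffix == ".mtx":
        return "mtx"
    if path.suffix == ".h5ad":
        return "h5ad"
    if path.suffix in (".csv", ".tsv", ".txt"):
        return "csv"
    raise ValueError(f"cannot infer format from {path}; pass format explicitly")


def read_expression(path, format: str | None = None, is_log: bool = True) -> ExpressionMatrix:
    """Read an expression matrix from MTX triplet, dense CSV/TSV, or H5AD.

    ``path`` for MTX is the directory holding ``matrix.mtx``, ``features.tsv``
    (or ``genes.tsv``) and ``barcodes.tsv``, or the ``matrix.mtx`` file
    itself.  Duplicate gene IDs are resolved by keeping the highest-mean row
    with a logged warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or _infer_format(path)
    if fmt == "mtx":
        mtx_dir = path if path.is_dir() else path.parent
        mtx_file = path if path.suffix == ".mtx" else mtx_dir / "matrix.mtx"
        feat = mtx_dir / "features.tsv"
        if not feat.exists():
            feat = mtx_dir / "genes.tsv"
        barc = mtx_dir / "barcodes.tsv"
        mat = spio.mmread(mtx_file)
        genes = pd.read_csv(feat, sep="\t", header=None)[0].astype(str).tolist()
        cells = pd.read_csv(barc, sep="\t", header=None)[0].astype(str).tolist()
        arr = mat.toarray() if sparse.issparse(mat) else np.asarray(mat)
        if arr.shape != (len(genes), len(cells)):
            raise ValueError(
                f"matrix shape {arr.shape} does not match {len(genes)} features "
                f"x {len(cells)} barcodes"
            )
        values = pd.DataFrame(arr, index=genes, columns=cells)
    elif fmt == "csv":
        sep = "\t" if path.suffix in (".tsv", ".txt") else ","
        values = pd.read_csv(path, sep=sep, index_col=0)
        values.index = values.index.astype(str)
        values.columns = values.columns.astype(str)
    elif fmt == "h5ad":
        import anndata

        adata = anndata.read_h5ad(path)
        x = adata.X.toarray() if sparse.issparse(adata.X) else np.asarray(adata.X)
        values = pd.DataFrame(
            x.T, index=adata.var_names.astype(str), columns=adata.obs_names.astype(str)
        )
    else:
        raise ValueError(f"unknown format {format!r}")
    return ExpressionMatrix(_dedup_genes(values), is_log=is_log)


def write_expression_mtx(mat: ExpressionMatrix, out_dir) -> None:
    """Write an MTX triplet (matrix.mtx + features.tsv + barcodes.tsv)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spio.mmwrite(out / "matrix.mtx", sparse.csr_matrix(mat.values.to_numpy()))
    pd.Series(mat.gene_ids).to_csv(out / "features.tsv", sep="\t", header=False, index=False)
    pd.Series(mat.cell_ids).to_csv(out / "barcodes.tsv", sep="\t", header=False, index=False)


def write_expression_h5ad(mat: ExpressionMatrix, path) -> None:
    import anndata

    adata = anndata.AnnData(
        X=mat.values.to_numpy().T,
        obs=pd.DataFrame(index=pd.Index(mat.cell_ids, name="cell")),
        var=pd.DataFrame(index=pd.Index(mat.gene_ids, name="gene")),
    )
    adata.write_h5ad(Path(path))


def read_metadata(path, cluster_col: str, true_type_col: str | None = None) -> ClusterMetadata:
    """Read a per-cell metadata CSV/TSV; the first column holds cell IDs."""
    path = Path(path)
    sep = "\t" if path.suffix in (".tsv", ".txt") else ","
    df = pd.read_csv(path, sep=sep, index_col=0)
    df.index = df.index.astype(str)
    return ClusterMetadata.from_frame(df, cluster_col, true_type_col)


def write_metadata(meta: ClusterMetadata, path) -> None:
    meta.table.rename_axis("cell").to_csv(Path(path))


def read_reference_tsv(path, is_log: bool = True) -> ReferenceMatrix:
    """Read a reference profile matrix TSV (first column gene ID)."""
    df = pd.read_csv(Path(path), sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return ReferenceMatrix(df, is_log=is_log)


def write_reference_tsv(ref: ReferenceMatrix, path) -> None:
    ref.values.rename_axis("gene").to_csv(Path(path), sep="\t")


def read_gene_list(path) -> list[str]:
    """Plain-text gene list, one gene per line; blanks skipped."""
    lines = Path(path).read_text().splitlines()
    return [ln.strip() for ln in lines if ln.strip()]


def write_gene_list(genes: list[str], path) -> None:
    Path(path).write_text("\n".join(genes) + "\n")


def read_marker_table(path) -> MarkerTable:
    """Read marker lists from long or wide CSV/TSV.

    Long format: columns ``type`` and ``gene`` (optional ``rank``, used to
    order the list).  Wide format: one column per type, genes in the rows;
    detected by the absence of a ``gene`` column.
    """
    path = Path(path)
    sep = "\t" if path.suffix in (".tsv", ".txt") else ","
    df = pd.read_csv(path, sep=sep)
    cols = {c.lower(): c for c in df.columns}
    if "gene" in cols and "type" in cols:
        if "rank" in cols:
            df = df.sort_values(cols["rank"], kind="stable")
        lists = {
            str(t): sub[cols["gene"]].astype(str).tolist()
            for t, sub in df.groupby(cols["type"], sort=True)
        }
        return MarkerTable(lists)
    lists = {
        str(c): df[c].dropna().astype(str).tolist() for c in df.columns
    }
    return MarkerTable(lists)


def write_marker_table(markers: MarkerTable, path) -> None:
    rows = [
        {"type": t, "gene": g, "rank": i + 1}
        for t in markers.types
        for i, g in enumerate(markers[t])
    ]
    pd.DataFrame(rows).to_csv(Path(path), index=False)


def read_call_table(path) -> CallTable:
    df = pd.read_csv(Path(path), sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return CallTable(df)


def write_call_table(calls: CallTable, path) -> None:
    calls.table.rename_axis("cluster").to_csv(Path(path), sep="\t")


def write_correlation_tsv(values: pd.DataFrame, path) -> None:
    values.rename_axis("cluster").to_csv(Path(path), sep="\t")
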