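"""Synthetic scRNA-seq fixtures with planted cell-type structure.

The generator draws negative-binomial counts for K cell types.  Each gene has
a baseline mean drawn once from a lognormal distribution (real transcriptomes
span orders of magnitude in baseline expression; this shared gene-level
structure is what makes pseudobulk profiles of the *same* type correlate
strongly between independent samples).  Each type additionally owns a
disjoint block of signature genes whose mean is multiplied by a fold change,
which is what separates the types from each other.

Signature (marker) genes behave the way real markers do: expressed well above
baseline in the type that owns them and near-silent in every other type
(baseline x fold in the owning type, baseline / fold elsewhere, so a fold
change of 1 degenerates to a structureless genome).

Counts are log1p-transformed to emulate normalized input.  The reference is
built by averaging an *independent* replicate draw, so query and reference
never share sampling noise and self-classification is a genuine test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import ClusterMetadata, ExpressionMatrix, MarkerTable, ReferenceMatrix
from .reference import average_clusters


@dataclass
class SyntheticSpec:
    """Parameters of the planted-structure generator.

    Attributes
    ----------
    n_types
        Number of cell types (clusters).
    cells_per_type
        Cells drawn per type in the query (and in the reference replicate).
    n_genes
        Total genes; must accommodate all signature blocks.
    n_signature_genes_per_type
        Size of each type's disjoint up-regulated block.
    signature_fold_change
        Multiplier (> 1) applied to a type's signature-gene means.
    nb_dispersion
        Negative-binomial size parameter theta; variance = mu + mu^2/theta.
    baseline_mean
        Median of the lognormal per-gene baseline means (counts scale).
    baseline_log_sd
        Log-scale SD of per-gene baseline means; 0 gives a flat genome.
    seed
        Seed for all randomness; identical seeds give bit-identical output.
    """

    n_types: int = 5
    cells_per_type: int = 100
    n_genes: int = 2000
    n_signature_genes_per_type: int = 20
    signature_fold_change: float = 8.0
    nb_dispersion: float = 2.0
    baseline_mean: float = 0.5
    baseline_log_sd: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if self.n_types < 1 or self.cells_per_type < 1 or self.n_genes < 1:
            raise ValueError("n_types, cells_per_type and n_genes must be positive")
        if self.n_types * self.n_signature_genes_per_type > self.n_genes:
            raise ValueError("signature blocks do not fit in n_genes")
        if self.signature_fold_change < 1:
            raise ValueError("signature_fold_change must be >= 1")
        if self.nb_dispersion <= 0 or self.baseline_mean <= 0:
            raise ValueError("nb_dispersion and baseline_mean must be > 0")
        if self.baseline_log_sd < 0:
            raise ValueError("baseline_log_sd must be >= 0")


def _nb_counts(rng: np.random.Generator, mean: np.ndarray, theta: float) -> np.ndarray:
    """NB draws with mean ``mean`` and dispersion theta (gamma-Poisson)."""
    p = theta / (theta + mean)
    return rng.negative_binomial(theta, p)


def _draw_matrix(
    rng: np.random.Generator,
    type_means: np.ndarray,  # genes x types
    cells_per_type: int,
    theta: float,
) -> np.ndarray:
    """Counts for cells_per_type cells of each type, genes x cells."""
    n_genes, n_types = type_means.shape
    blocks = []
    for t in range(n_types):
        mu = np.repeat(type_means[:, [t]], cells_per_type, axis=1)
        blocks.append(_nb_counts(rng, mu, theta))
    return np.concatenate(blocks, axis=1)


def generate_dataset(
    spec: SyntheticSpec,
) -> tuple[ExpressionMatrix, ClusterMetadata, ReferenceMatrix, MarkerTable]:
    """Draw a query matrix, its metadata, a matched reference and marker lists.

    The metadata carries the generating type both as the cluster label and as
    ``true_type``.  The reference averages an independently drawn replicate of
    the same generative means; markers are each type's signature genes.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    gene_ids = [f"gene{g:05d}" for g in range(spec.n_genes)]
    type_labels = [f"type{t}" for t in range(spec.n_types)]

    # Per-gene lognormal baseline with median spec.baseline_mean.
    baseline = spec.baseline_mean * np.exp(
        rng.normal(0.0, spec.baseline_log_sd, size=spec.n_genes)
    )
    type_means = np.repeat(baseline[:, None], spec.n_types, axis=1)
    markers: dict[str, list[str]] = {}
    k = spec.n_signature_genes_per_type
    for t in range(spec.n_types):
        block = slice(t * k, (t + 1) * k)
        # markers: fold-change up in the owning type, symmetrically silenced
        # elsewhere; at fold == 1 the block collapses to baseline (no structure)
        type_means[block, :] = baseline[block, None] / spec.signature_fold_change
        type_means[block, t] = baseline[block] * spec.signature_fold_change
        markers[type_labels[t]] = gene_ids[block]

    query_counts = _draw_matrix(rng, type_means, spec.cells_per_type, spec.nb_dispersion)
    ref_counts = _draw_matrix(rng, type_means, spec.cells_per_type, spec.nb_dispersion)

    cell_ids = [f"cell{c:05d}" for c in range(query_counts.shape[1])]
    labels = np.repeat(type_labels, spec.cells_per_type)
    query = ExpressionMatrix(
        pd.DataFrame(np.log1p(query_counts), index=gene_ids, columns=cell_ids),
        is_log=True,
    )
    meta = ClusterMetadata(
        pd.DataFrame({"cluster": labels, "true_type": labels}, index=cell_ids)
    )

    ref_cell_ids = [f"refcell{c:05d}" for c in range(ref_counts.shape[1])]
    ref_mat = ExpressionMatrix(
        pd.DataFrame(np.log1p(ref_counts), index=gene_ids, columns=ref_cell_ids),
        is_log=True,
    )
    ref_meta = ClusterMetadata(pd.DataFrame({"cluster": labels}, index=ref_cell_ids))
    reference = average_clusters(ref_mat, ref_meta, if_log=True)

    return query, meta, reference, MarkerTable(markers)
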