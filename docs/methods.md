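# Methods

## Classification model

A query cluster is summarized by its pseudobulk profile: the per-gene mean
of its cells' normalized expression. When the input is on the log1p scale
the mean is taken in linear space (expm1 → arithmetic mean → log1p), so the
profile approximates what a bulk assay of the pooled cells would measure;
callers who explicitly want a mean of log values can pass `if_log=False` on
linear-scale data. The profile is compared with each reference column over a
variable-gene set by a similarity coefficient, and the best-scoring type is
assigned unless its score falls below a cutoff, in which case the cluster is
*unassigned*.

Assumptions: cells within a cluster are of one type (the method annotates
clusters, not cells — per-cell mode exists but is noisier and not
recommended); the reference and query measure broadly comparable
transcriptomes; gene identifiers match exactly (no alias mapping). Rank
correlations (Spearman default, Kendall τ-b optional) are insensitive to
monotone differences in normalization between query and reference, which is
why Spearman is the default for cross-platform use. Cosine similarity is
computed on raw, uncentered values; with non-negative log-space input it is
therefore bounded below by 0 and inflated by shared baseline expression —
it is provided for completeness, not as the default.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `method` | spearman | similarity coefficient |
| `threshold` | 0.5 | minimum winning coefficient; `"auto"` = 0.8 × best observed (global by default, per-row optional) |
| `min_cells` | 10 | clusters below this size are warned about (or dropped in strict mode); averages of very few cells are unreliable |
| variable genes | top 1000 by reference variance, or caller-supplied | the gene subspace of the correlation; marker-dominated sets are what make rejection of unseen types possible |
| `power_x` | 0 | subclustering exponent: ⌊n^x⌋ k-means sub-profiles per reference cluster of n cells |
| `n_markers` | 100 | markers derived per query cluster for list-based metrics |
| list thresholds | hypergeom −log10 p ≥ 5; jaccard, pct, gsea ≥ 0 | calling cutoffs on the larger-is-better score scales |

Numeric conventions: tied ranks receive average (fractional) ranks;
zero-variance (or zero-norm) profiles yield NaN coefficients, which are
never winners and, alone in a row, produce *unassigned* with a NaN score;
argmax ties break to the lexicographically smallest type label; reference
columns are emitted in sorted order; top-variance gene selection uses
sample variance (ddof=1) with lexicographic tie-break. Consensus across
correlation methods takes the per-cluster modal call, with ties (including
1–1 splits) mapping to *unassigned*. Hypergeometric p-values are exact tail
sums of the probability mass, not normal approximations; −log10 p is capped
at 320 to stay finite in double precision. GSEA uses the classic weighted
Kolmogorov–Smirnov running sum (weight exponent 1) with a gene-permutation
null and a +1 pseudo-count on the permutation p-value; the permutation
count and seed are explicit arguments.

## Design choices that were genuinely open

- **Log-vs-linear averaging.** Averaging in linear space with re-log was
  chosen so cluster profiles emulate bulk measurements; the flag makes the
  alternative available rather than silently deciding.
- **`n^x` rounding.** ⌊n^x⌋ with a floor of 1; a cluster of one cell emits
  that cell's profile.
- **Subclustering gene space.** k-means for subclustering runs on the 1000
  top-variance genes of the whole matrix (k-means++ init, 10 restarts,
  fixed seed): full-genome k-means on log counts is dominated by noise
  dimensions, and 1000 genes matches the variable-gene default elsewhere.
- **Auto-threshold scope.** 0.8 × the *global* matrix maximum by default —
  a per-row variant (`auto_scope="row"`) is exposed, but the global form
  uses the best-attested correlation in the experiment as the yardstick for
  every cluster, which is the interpretation that lets weakly correlated
  clusters be rejected at all.
- **Gene-intersection contract.** Genes absent from either side of the
  comparison are dropped silently; the usable intersection size is logged,
  and a UserWarning fires below 100 genes, where coefficients become
  noticeably unstable.
- **Unassigned in F1.** For benchmarking, an *unassigned* prediction counts
  against its true type's recall and is never treated as a predicted class;
  without this rule rejection behaviour would be unscoreable. In cluster
  accuracy, rejection is credited as correct only in strict-rejection mode
  when the true type is genuinely absent from the reference.
- **Hypergeometric universe.** Defaults to the union of the active gene
  sets (matrix genes ∪ reference markers when a matrix is present);
  overridable, since the "right" universe is a modelling choice.

## The synthetic generator

The generator emulates the minimal structure the classifier relies on:

- per-gene baseline means drawn once from a lognormal distribution
  (median `baseline_mean` = 0.5 counts, log-SD `baseline_log_sd` = 0.5) —
  real transcriptomes span orders of magnitude in baseline expression, and
  this shared gene-level structure is why independent pseudobulk samples of
  the same type correlate strongly;
- K disjoint signature blocks (default 5 types × 20 genes) at
  baseline × fold in the owning type and baseline / fold elsewhere
  (default fold 8): markers are expressed in their type and near-silent
  everywhere else. At fold 1 both sides collapse to baseline and the genome
  carries no type structure;
- negative-binomial counts (gamma–Poisson, dispersion θ = 2, so
  var = μ + μ²/2), log1p-transformed;
- the reference is the per-type average of an *independent* replicate draw,
  so query and reference share no sampling noise;
- marker lists are the signature blocks themselves.

With these defaults and the query's top-100 variance genes (5% of the
2000-gene toy genome, the scaled-down analogue of ~1000 highly variable
genes of a mammalian transcriptome), matching cluster–type pairs correlate
at ρ ≈ 0.86–0.92, non-matching pairs at ≤ 0.37, and a cluster whose type is
removed from the reference peaks below ≈ 0.35 — comfortably either side of
the 0.5 cutoff. The near-silent off-state is load-bearing for rejection: if
markers kept their full baseline expression in non-owning types, the
held-out cluster would correlate with every remaining type through the
shared baseline alone and could never be rejected at 0.5. Variable genes
should be computed from the *query* for rejection to work — a
reference-derived list cannot contain the markers of a type the reference
lacks.

What the generator does **not** emulate: batch effects, library-size
variation (counts are drawn directly at the gene mean), doublets, ambient
RNA, correlated gene modules beyond the planted blocks, and continuous or
hierarchical cell states. Passing the synthetic benchmarks therefore shows
the machinery is correct and well-calibrated on cleanly separated types; it
does not certify performance on data where types blend into gradients or
where technical structure rivals biological signal.

## Problem sizes used in tests and the acceptance script

The shipped benchmarks run the default fixture (5 types × 100 cells × 2000
genes), 20 leave-one-type-out replicates, a 15-cells-per-cluster
downsampled variant, 50 random small instances per correlation method
against naive brute-force oracles, and the complete hypergeometric
configuration sweep for universes up to 25 with set sizes up to 8 — sizes
chosen so the full suite completes in seconds while every code path and
calibration claim is exercised end to end.

## Known limitations

- Exact, case-sensitive gene-ID matching; cross-species or symbol-version
  mismatches must be resolved upstream.
- Kendall correlation is computed pairwise per (cluster, type) and is the
  slowest method on large references.
- The auto-threshold heuristic is undefined on an all-NaN matrix (no finite
  coefficient); such rows are unassigned by construction.
- Scores carry no p-values or calibration; they are rankings with a cutoff,
  by design.
- Seurat RDS and loom inputs are not parsed; export to MTX/CSV/H5AD first.
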