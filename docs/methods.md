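# Methods

## Model and assumptions

The true expression matrix is assumed non-negative and low-rank — genes act
in correlated modules, so expression profiles lie near a subspace of
dimension far below the number of cells or genes — and to contain many true
(biological) zeros. The observed matrix is a corrupted version in which
sampling noise has replaced some entries, most visibly as technical zeros.
Imputation is therefore *not* a standard low-rank matrix-completion problem:
the set of observed entries is unknown, because the missing entries are an
unknown subset of the observed zeros, a strongly biased sampling that voids
completion guarantees.

ALRA instead relies on one empirical (and, under assumptions, provable)
property of the rank-k SVD reconstruction `Y` of the normalized matrix: the
entries of `Y` at biological-zero positions are symmetrically distributed
around zero, approximately Gaussian, gene by gene. The negative values of a
gene — which can only be reconstruction error, since the data are
non-negative — therefore estimate the error distribution of that gene's
biological zeros, and thresholding at the magnitude of the lower `p`-quantile
removes them with probability about `1 − p` while leaving genuinely expressed
entries (which sit far above the threshold) intact.

The key failure mode is weak signal: when cell populations are homogeneous,
leading singular values are small relative to noise, singular vectors are
poorly estimated, and both rank selection and the symmetry property degrade.
ALRA is intended for datasets containing a diversity of cell states.

## Pipeline parameters

| parameter | default | units / range | role |
| --- | --- | --- | --- |
| `alpha` | 10,000 | transcripts/cell | library-normalization target before log1p |
| `k` | auto | 1 … min(n,m) | rank of the approximation; `None` = spacing rule |
| `quantile_p` | 0.001 | (0, 0.5) | per-gene threshold quantile level |
| `n_singular_values` | 100 | — | spectrum length for rank selection (assumed k < 100) |
| `q_rank` | 2 | iterations | power iterations for the rank-selection spectrum (cheap) |
| `q_svd` | 10 | iterations | power iterations for the rank-k SVD (accurate) |
| `noise_start` | 80 | spacing index | first spacing of the noise window |
| `rescale` | on | — | per-gene non-zero moment matching |
| `restore` | on | — | restore observed entries zeroed in thresholding |

Results are insensitive to moderate changes in `alpha` and `p`; both are
exposed rather than hardcoded. The natural logarithm is used (the choice of
base is structurally irrelevant). Cell/gene filtering thresholds default to
off — values like "cells expressing more than 400 genes, genes expressed in
more than 100 cells" are dataset-level choices, exposed as strict (`>`)
inequalities on the CLI and in `filter_counts`, cells filtered before genes.

## Rank selection

The spectrum is descending, so the non-negative spacing is defined as
`d_j = σ_j − σ_{j+1}` (j = 1 … K−1) and the selected rank is the *largest* j
with `d_j` strictly above `μ + 6s`, where `μ` and `s` (sample sd, n−1) are
computed over the noise window `d_80 … d_99` — 20 spacings for the default
100-value spectrum. When fewer than `noise_start + 1` spacings exist (small
matrices reduce `n_singular_values` automatically, with a warning), the
window falls back to the last 20% of spacings, at least 5. Strict comparison
means a perfectly flat spectrum (s = 0, all spacings equal to μ) raises a
no-signal error with advice to pass `k` explicitly, rather than returning a
spurious rank.

On spiked-matrix simulations the rule never misses a planted spike (k ≥ r in
every trial we run), but it can overshoot by 1–2 when the noise spectrum has
a sharp bulk edge: the first bulk spacings after Tracy–Widom fluctuation are
several times larger than spacings deep in the bulk where the noise window
sits, and occasionally exceed μ + 6s. This is a property of the selection
rule itself, not of the SVD backend (an exact spectrum overshoots slightly
more often than the randomized one). ALRA's downstream metrics are flat in k
over such small overshoots, which is the practical justification for the
rule.

## Thresholding, rescaling, restoration

Quantiles use linear interpolation between order statistics (quantile 0 =
minimum); with `p = 0.001` and fewer than ~1,000 cells the threshold is
effectively the magnitude of the gene's most negative reconstructed value.
The quantile is taken over *all* cells of a gene, and the absolute value
applied afterwards. Thresholding is strict (`y < τ` → 0): a value exactly at
the threshold — the observed mirror point — survives; the boundary has
measure zero on real data.

Rescaling affinely maps each gene's surviving non-zero values so their mean
and sample standard deviation (n−1) match those of the gene's non-zero
normalized values. Genes with fewer than two non-zero entries on either
side, or zero spread on either side, pass through unscaled — the moments are
undefined and silent identity is safer than extrapolation. Values driven
negative by the map are clamped to exactly 0.

Restoration is the final step and applies to every entry that is zero after
rescaling but non-zero in the normalized matrix, whether it was zeroed by
thresholding or clamped during rescaling: the output never destroys an
observed value, so `zeros(imputed) ⊆ zeros(observed)` holds unconditionally
when restoration is on. Rescaling moments are computed before restoration.

Genes never detected in any cell are orthogonal to every singular vector
with non-zero singular value, so their reconstruction is identically zero in
exact arithmetic; the implementation enforces this against floating-point
noise (without it, ~1e−15 residuals would flip zero-pattern bits between SVD
backends).

## Simulator

The simulator reproduces the multinomial validation design: each cell picks
one of S bulk profiles uniformly at random (weights exposed), and its counts
are a single draw from `Multinomial(round(depth_scale · N_ℓ), p)`, where `p`
is the chosen bulk profile normalized to sum to one. Genes with zero bulk
counts have sampling probability exactly 0 and form the cell's ground-truth
biological zeros; expressed genes drawn zero are technical zeros, occurring
at rate `(1 − p_j)^N` exactly as in the sampling-zero model. `depth_scale`
(α ∈ (0, 1]) scales depth to emulate shallower sequencing.

Synthetic bulk profiles stand in for real purified-population data (labelled
synthetic throughout): per-gene base abundance ~ LogNormal(4, 1.5) shared
across samples, per-sample LogNormal(0, 0.5) fold changes, rounded and
floored at one read; each sample receives `zero_fraction · m` biological-zero
genes of which a fraction `overlap` (default 0.5) is shared by all samples.
Depths are LogNormal with median 2,000 and log-sd 0.5 by default —
CV ≈ 0.53, typical of droplet libraries — or user-supplied. What the
simulator does *not* model: within-type heterogeneity (cells of a type are
i.i.d.), UMI/PCR noise beyond multinomial sampling, batch effects, and
ambient RNA. Passing tests on it therefore demonstrate correct behavior of
the zero mechanics and the symmetry-based thresholding, not robustness to
real-data artifacts; the fold-change model also makes essentially every gene
differential between types, a stronger type signal than related immune
populations exhibit.

## Diagnostics and metrics

`ψ_i = #{0 < y < τ_i at observed zeros} − #{y < 0 at observed zeros}`
estimates the technical zeros a gene leaves unimputed: under pure symmetry
the two counts match, and a surplus of sub-threshold positives indicates
dropouts indistinguishable from biological zeros. ψ is reported per gene
with its components; the median across genes is the robust summary (the mean
is dominated by a heavy upper tail of lowly-expressed genes, and genes whose
values at observed zeros exceed τ contribute negatively).

Symmetry summaries (`zero_position_stats`) report mean, sd, adjusted
Fisher–Pearson skewness and quantiles of the low-rank values at masked
positions, for genes with at least 200 such positions by default —
small-sample skewness is noise. Zero-spread genes are flagged (skewness
NaN) rather than dropped.

ZP (fraction of entries in biological-zero genes still zero after
imputation), TC (fraction of observed zeros completed) and the simulation
percentages depend only on zero patterns and are invariant to monotone
transforms of the values. "Zero" means exactly 0.0 — ALRA produces exact
zeros by construction. The Gini coefficient uses the population (n²)
denominator with no small-sample correction; several conventions exist and
this one is stated. Cell-to-bulk correlation classification places both
sides on the same log1p CP-α scale, breaks ties toward the lowest sample
index, and excludes (with a warning) cells whose expression is constant.

## Numerical and design choices

* Randomized SVD is `sklearn.utils.extmath.randomized_svd` with QR-normalized
  power iterations; `svd_method="exact"` (full SVD, truncated) provides the
  oracle path used in dual-route tests. Both are seeded; fixed seeds give
  bit-identical runs.
* The dense rank-k matrix is materialized once (O(cells·genes) memory at
  k ≤ 100); factors are retained for provenance.
* The estimator is transductive: `fit_transform(X)` is canonical.
  `transform` projects new cells onto the fitted right singular subspace and
  applies the fitted thresholds and gene maps — it matches the in-sample
  result up to randomized-SVD accuracy and exactly under the exact backend.
* Problem sizes in the test suite (up to 2,000 × 2,000 simulations, 500 × 300
  spiked matrices, 20 seeds per condition) were chosen so the whole suite
  runs in a few minutes on one core while keeping binomial/Tracy–Widom
  sampling error well below the asserted margins.

## Known limitations

* Homogeneous datasets (single cell type) can defeat both rank selection and
  the symmetry property; the no-signal error is deliberate.
* The 6s spacing rule can overshoot the planted rank near a sharp noise-bulk
  edge (see above); downstream results are insensitive, but exact rank
  recovery should not be expected in that regime.
* At small selected ranks, the log transform's curvature leaves systematic
  per-gene offsets in the reconstruction at biological-zero positions that
  can exceed a few percent of the within-gene spread; the offsets shrink as
  k grows and do not materially affect zero preservation (the thresholds
  adapt per gene), but strict mean-zero symmetry at the 0.05·sd level holds
  for only ~60–70% of genes on the default simulation rather than ~90%.
* Rescaling can clamp; clamped entries are restored only if observed
  non-zero, otherwise they remain zero.
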