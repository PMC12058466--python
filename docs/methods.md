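# Methods

`protnorm` benchmarks normalization and batch-effect correction methods for
protein-level quantification data (label-free or TMT). This note documents
the models, the concrete numerical choices, and what the synthetic
benchmark does and does not show.

## Data model

The central object is a proteins × samples intensity matrix with an
explicit scale flag (`raw` or `log2`), per-protein boolean annotation flags
(decoy, contaminant, spike-in) and ordered sample metadata (condition,
optional TMT batch, optional pooled-reference flag). Zero intensities in
MaxQuant-style tables are treated as non-detections and stored as missing;
missingness is carried as a mask and never silently imputed. All
normalization methods return a log2-scale matrix regardless of the scale
they operate on internally, so downstream DE testing and metrics have a
single contract.

## Preprocessing

* **Missing-value filter**: keep a protein if its observed fraction meets a
  threshold, either overall (default) or within every condition.
* **Missingness classes**: a protein missing in *all* replicates of at
  least one condition is missing-not-at-random (MNAR, low-abundance
  censoring); other incomplete proteins are missing-at-random (MAR);
  the rest are complete.
* **Mixed imputation** (log2 scale): MAR cells are filled with the mean of
  the k nearest proteins (k = 10; Euclidean distance over shared observed
  samples after per-row standardization, so similarity reflects profile
  shape rather than absolute abundance). MNAR cells are drawn from
  Normal(m_j − shift·s_j, (width·s_j)²) with m_j, s_j the observed mean and
  SD of sample j; defaults shift = 1.8, width = 0.3, the common
  left-shifted-Gaussian convention. MAR proteins without a usable
  neighbour fall back to the MNAR draw (logged). All draws come from one
  seeded generator.
* **Outlier detection**: per condition group, each sample's Euclidean
  distance (complete-case proteins, log2 scale) to the group centroid is
  compared with a Tukey fence Q3 + 1.5·IQR over the group's distances
  (linear-interpolation quartiles). Size-1 groups warn and never flag.

## Normalization methods

All 17 methods plus the unnormalized `log2` baseline share one contract:
shape and missingness mask preserved, output on log2 scale, fitted
parameters retained. Each method is applied internally on the scale it is
conventionally defined on — raw for mean/median/global/TMM/VSN/Normics,
log2 for MAD/quantile/regression/loess/EigenMS/RobNorm.

* **mean / median**: multiply each raw column by grand-statistic /
  column-statistic. **global_mean / global_median**: same with the column
  sum as statistic. Note that the equal-column-median guarantee is exact on
  the raw scale; for columns with an even number of observed values the
  log2-scale medians can differ at ~1e-4 because the midpoint average does
  not commute with the logarithm.
* **mad**: center each log2 column at its median and divide by its MAD
  (consistency constant 1.4826). By default no common scale is re-added;
  this is what compresses fold changes under MAD (a `rescale_mad` option
  re-adds the grand median for users who want comparable magnitudes).
* **quantile**: mean empirical quantile function as reference; observed
  values are replaced by the reference evaluated at their average-rank
  quantile positions (interpolated, so columns with missing values are
  handled without imputation).
* **rlr / rlr_ma / rlr_ma_cyc**: robust straight-line fits (Huber
  M-estimation, c = 1.345, via statsmodels RLM; ordinary LS fallback for
  exact fits where the robust scale degenerates). The reference
  pseudo-sample is the row-wise median. Cyclic variant: every ordered
  sample pair per cycle, corrections halved and applied symmetrically,
  3 cycles, fixed ascending pair order.
* **loess_f / loess_cyc**: degree-1 lowess (span 0.7, 2 robustifying
  iterations, delta shortcut 0.5% of the A-range) of M on A against the
  row-mean reference (loess_f, one pass) or pairwise with half-corrections
  (loess_cyc, 3 cycles).
* **tmm**: trimmed mean of M-values on raw scale. Library sizes are column
  sums over observed values; the reference sample minimizes the distance of
  its 75th percentile of x/N from the mean of those. Two-sided trims of
  30% on M and 5% on A, binomial delta-method precision weights, factors
  rescaled to geometric mean 1.
* **vsn**: per-sample affine-arsinh transform h_j(x) = arsinh(a_j + b_j x)/ln 2,
  behaving like log2 at high intensity and linear near zero. The fit
  minimizes the profile negative log-likelihood
  (N/2)·log RSS − Σ log h′_j(x_ij) by iterated least-trimmed selection
  (default lts_quantile 0.9: the 90% of proteins with smallest row residual
  SS drive the fit) with cyclic per-sample Nelder–Mead updates and a final
  joint Powell refinement. The Jacobian term is required: a pure
  least-squares objective is degenerate (RSS → 0 as all b_j → 0). One
  direction remains exactly flat — a common additive shift of the
  transformed matrix — so comparisons between fits are made after
  centering. Init: a_j = 0, b_j = grand median / column median; 10 outer
  iterations.
* **normics_median / normics_vsn**: invariant-protein normalization.
  Complete proteins are scored by the variance across samples of their
  deviation from the column median; the n most stable form the invariant
  set S (default min(100, 10% of proteins)). The median variant shifts each
  sample so its median over S is common; the VSN variant estimates
  (a_j, b_j) on S only and applies the transform to all proteins.
  Excluding regulated proteins keeps factors from absorbing real signal.
* **eigenms**: complete-case proteins are centered within their condition
  group; the residual matrix is decomposed by one SVD, and the t-th
  eigenvalue fraction is tested against the t-th fraction of 99 within-row
  permutations (re-group-centered), stopping at the first non-significant
  trend (α = 0.05). Each protein's group-centered residuals are then
  projected onto the significant right-singular vectors (restricted to its
  observed samples) and the projection subtracted. Testing the undeflated
  spectrum is deliberate: a deflate-and-retest scheme is anti-conservative
  because deflation reduces the observed rank but not the permuted null's,
  and in our checks it removed every possible trend (collapsing
  within-group variance). The implemented test has a measured false-trend
  rate of ~α on pure-noise data. Rows are processed in protein-id order so
  results do not depend on input row order.
* **robnorm**: model x_ij = μ_i + s_j + ε_ij, ε ~ N(0, σ_i²) on log2.
  Density-power weights w = exp(−γ r²/(2σ_i²)) (γ = 0.5) iterate weighted
  updates of μ and s (s centered to zero mean) from a median-based
  initialization until max|Δs| < 1e-6. σ_i is re-estimated each iteration
  as 1.4826·MAD of the protein's residuals — a w-weighted variance would
  let outlying cells inflate their own σ and escape downweighting — and is
  floored at 1e-6 absolutely and at 1% of the median σ² relatively, so a
  few near-perfectly fitted proteins cannot monopolize the weights. γ = 0
  reduces to σ-weighted least squares.

## Batch correction

* **IRS** (raw scale): per protein, the geometric mean over each batch's
  pooled-reference channels (all batch samples when none are designated)
  is scaled to the cross-batch geometric mean of those references;
  proteins without an observed reference in a batch stay uncorrected there
  and are recorded. Computed as arithmetic means on log2.
* **limBE** (log2 scale): per protein, least squares with intercept +
  condition indicators plus sum-to-zero-coded batch covariates; the fitted
  batch component is subtracted. Sum-to-zero coding guarantees that
  condition means are untouched; perfectly confounded batch/condition
  partitions are rejected. Note that adding a constant to one batch is
  absorbed only up to a global intercept shift, which is irrelevant for
  fold changes and variances.
* Compositions run in either order (default: normalize first, then
  correct); IRS after a log2-producing method exponentiates internally.

## Evaluation metrics

* **PMAD**: mean over proteins of the within-group MAD (×1.4826; the
  constant is a documented choice, the definition is constant-agnostic),
  proteins with <2 observed group values skipped. Reduction is reported as
  100·(1 − PMAD/PMAD_log2).
* **Intragroup Pearson** for every within-group sample pair,
  pairwise-complete, pairs sharing <3 proteins skipped.
* **PCA silhouettes**: samples are embedded on the first three PCs of the
  complete-case, protein-centered (unscaled by default, flag available)
  matrix, with a deterministic sign convention; silhouettes
  S_j = (b_j − a_j)/max(a_j, b_j) on Euclidean distances, singleton groups
  scored 0. The mean silhouette under the batch grouping ("batch
  coefficient") near 1 diagnoses batch effects; under the condition
  grouping it measures biological signal.
* **Hierarchical clustering**: average-linkage on Euclidean distances over
  complete-case proteins, deterministic leaf order.

## Differential expression

* **Moderated t**: per protein, logFC = mean(Case) − mean(Control) (so
  positive logFC means higher in Case), pooled variance with df d,
  posterior variance (d0·s0² + d·s²)/(d0 + d), t on d0 + d df (standard
  normal when d0 = ∞). The prior (d0, s0²) is estimated by method of
  moments on log s² (digamma/trigamma matching with a Newton trigamma
  inverse); when residual dfs are mixed due to missing values the prior is
  fitted on proteins with the modal df. d0 = 0 recovers the ordinary
  pooled t-test exactly.
* **ROTS**: statistic family |x̄₁ − x̄₂|/(α₁ + α₂·SE) spanning the plain
  difference (1, 0) and a t-like statistic (0, 1); (α, k) chosen to
  maximize the standardized excess of bootstrap top-k reproducibility over
  a label-permuted null (defaults B = 100 bootstrap pairs, k grid
  {25, 50, 100, 200, 400} ∩ [1, n/2], α₁ grid
  {0, .01, .05, .1, .25, .5, 1, 2, 5}). P-values come from label
  permutations of the selected statistic pooled over proteins
  (n_perm = 500), then BH. The pooled permutation p-values are calibrated
  on null data (measured fraction p < 0.05 ≈ 0.05).
* **BH** step-up per (method, comparison) family at 0.05; missing p-values
  are excluded and reinserted. DE calls additionally require
  |logFC| > threshold — 1 by convention for biological data, 0 for
  spike-in evaluations.

## Ground-truth scoring and method comparison

A spike-in protein called DE is a true positive and a false negative
otherwise; a background protein called DE is a false positive. F1 uses
precision and recall (0 when TP = 0); FPR = FP/(FP + TN). AUC is the
tie-corrected Mann–Whitney statistic on the −log10 raw p ranking
(monotone-equivalent to the |t| ranking at fixed df). Expected logFCs are
log2 concentration ratios (0 for background); accuracy is summarized by
the median background logFC and the median spike-in bias. Without truth,
methods are compared by up/down DE counts, pairwise Jaccard similarity of
DE sets (J(∅,∅) = 1), consensus intersections, and ranking by median F1
with paired two-sided Wilcoxon signed-rank tests against the top method
(exact for n ≤ 25; the "paired rank-sum" of common usage is this test).

## Synthetic data

The generator emulates the spike-in experimental design: on log2 scale,
x_ij = μ_i + δ_i(cond(j)) + s_j [+ b_k + g_ik] + ε_ij with baselines
μ_i ~ U(20, 30), spike-in effects δ = log2 of the known concentration
ratio (0 for the constant background), sample shifts s_j ~ N(0, shift_sd²)
— the systematic bias normalization should remove — optional TMT batch
offsets b_k ~ N(0, batch_sd²) with protein×batch interactions at half that
SD and optional pooled reference channels (content = the average
condition), and noise ε ~ N(0, σ_i²), σ_i ~ U(noise_sd_range). MAR
missingness is uniform Bernoulli; MNAR follows a logistic censoring curve
in log2 intensity. Named scenarios fix the study conditions:

* `default`: 2700 background + 300 spike-in proteins (10% spike rate,
  ratio 2), two conditions × 4 replicates, shift_sd 0.5, σ ∈ (0.1, 0.4) —
  a clean LFQ-like design.
* `tmt3x`: 1200 + 120 proteins, 2 × 6 samples over 3 TMT batches,
  batch_sd 1.0, pooled reference channel per batch.
* `asymmetric-spike`: 800 + 200 proteins (20% spike rate, ratio 4
  concentrated in one condition) — the regime in which global shifting
  factors absorb the spike signal and shift the background.

What the generator does *not* emulate: biological replicate variation,
peptide-level effects and rollup, intensity-dependent (nonlinear) bias
except where tests inject it explicitly, correlated protein modules, and
the compositional interplay of real spike-in mixtures. Passing tests
therefore demonstrate internal correctness and the *directional*
reproduction of benchmark phenomena (MAD's fold-change compression,
shifting methods' FPR inflation under asymmetric spike-ins, EigenMS's FP
excess, limBE's batch-silhouette reduction), not performance claims about
any real dataset.

On the heavy-tailed-null comparison of the DE tests: with calibrated
pooled-permutation p-values, ROTS shows no FP advantage on *pure* null
data (both tests are at or below nominal level there). The false-positive
reduction appears — and is tested — in the spike-in regime with
heavy-tailed, heteroscedastic noise and residual normalization bias,
where the moderated t's variance shrinkage produces excess background
calls at the BH level.

## Problem sizes and numerics

The shipped test-suite and acceptance runs use the scenario sizes above
(up to 3000 × 8), 99 permutations for EigenMS, B = 100/n_perm = 500 for
ROTS (reduced to 50/300 inside multi-seed loops), 200 runs for
calibration-rate estimates, and ≥10 seeds for every directional claim —
sizes chosen so the full benchmark reruns in minutes on one CPU while
keeping Monte-Carlo error well inside the asserted tolerances. Iterative
fits are deterministic given the seed; known degenerate inputs (zero MAD
columns, confounded designs, single-batch IRS, one-sample groups,
sub-minimal replication) raise explicit errors or are excluded and
counted rather than silently patched.
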