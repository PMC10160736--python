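# Methods

## Pseudo-bulk construction and normalization

Cells are summed gene-wise per sample (`aggregate_cells`); the pipeline
order is sample filtering (default: ≥ 50 cells, library threshold 0),
gene filtering (default: ≥ 30 reads summed over samples, strict `<`
removal), then TMM normalization. TMM uses a 30% two-sided trim on
log-ratios (M), a 5% trim on average log-intensity (A), inverse-variance
precision weights from the asymptotic binomial variance of M, and as
reference the sample whose 75th-percentile CPM is closest to the mean of
those percentiles (lowest index on ties, so runs are deterministic);
factors are rescaled to geometric mean 1. log-CPM follows the voom
dialect exactly — log2((count + 0.5)/(lib·factor + 1)·10⁶) — because the
weight interpolation downstream assumes this offset structure.

## voom and its group-aware variants

`voom` fits per-gene least squares of log-CPM on the design, regresses
√(residual SD) on average log2 count with LOWESS (span 0.5, two
robustifying iterations, interpolation shortcut `delta = 0.01 ×` x-range as
in the classical implementation), and evaluates the curve at each
observation's fitted log-count to form weights lo(λ̂)⁻⁴. Prediction is
linear between fitted points and **constant beyond the training range**, so
extreme fitted values cannot blow up the weights; predicted √SD is floored
at 10⁻⁴. Genes with (near-)zero residual variance are excluded from trend
training but still receive interpolated weights; fewer than 10 usable
training points is an error that directs the caller to the overall trend.

`voom_qwb` estimates per-sample variance factors exp(γ_i) under
var(ε_gi) = σ_g² exp(γ_i), with γ parameterized per experimental group
("blocked") or per sample. The estimator iterates (a) gene-wise weighted
fits and (b) a method-of-moments update of each block's γ from
leverage-corrected standardized squared residuals pooled over genes
(E[w r²/σ̂²] = 1 − h at the truth), to convergence (max |Δγ| < 10⁻⁶, cap
50 iterations; non-convergence returns the last iterate with a flag).
Sample weights 1/exp(γ̂) are normalized to geometric mean 1 (γ is only
identified up to a constant). The full pipeline alternates voom and weight
estimation twice (`n_iter = 2`): voom → weights → voom(with sample weights
in the fits) → weights → combine w* = w × sample_weight. The alternation
count is exposed because the marginal change after the second pass is
already far below Monte-Carlo noise in every benchmark quantity.

`voom_by_group` computes log-CPM, library sizes and TMM factors **once on
all samples** (weights must be commensurable in the joint fit), then per
group subsets the expression columns and design rows, drops design columns
that become identically zero, and falls back to an intercept-only design if
the remainder is rank-deficient or leaves no residual df — a defined
fallback instead of an undefined crash when covariates exhaust the subset's
degrees of freedom. Group trends are fitted on the subset residual SDs;
weights use the group trend at the subset fitted log-counts with the global
effective library sizes. Groups flagged `dynamic` (default: ≤ 2 samples)
take the overall voom weights for their columns, which makes "all groups
dynamic" reduce to plain voom exactly, as does a single group spanning all
samples. The method targets single-factor designs; multi-factor covariate
adjustment is better served by `voom_qwb`.

## Moderated testing

Contrast fits return logFC = cᵀβ̂ and unscaled SD √(cᵀ(XᵀWX)⁻¹c). The
scaled inverse-chi-square prior on σ_g² is fitted by moment matching on
log s² (solve trigamma(d0/2) = var(e) − trigamma(df/2) by Newton on the
trigamma inverse; s0² from the bias-corrected mean), not maximum
likelihood, and without winsorizing. When the spread of log s² does not
exceed its chi-square sampling expectation the prior degenerates
(d0 = ∞) and the posterior is the common value exp(mean log s²).
Moderated t uses df = df_resid + d0 (normal reference when d0 = ∞);
p-values are two-sided; BH adjustment is applied per contrast across all
retained genes; tables sort by p with a stable gene-ID tie-break.

## Common dispersion / BCV

The group-wise common NB dispersion maximizes the mean Cox–Reid adjusted
profile log-likelihood of intercept-only NB models with log effective
library sizes as offsets, by golden-section search on log10 φ ∈ [−4, 0.7]
(tolerance 10⁻⁴); BCV = √φ. The adjusted profile likelihood was chosen
over quantile-adjusted conditional likelihood because it handles unequal
library sizes without pseudo-count equalization; on simulated NB
pseudo-bulk the two agree to about three decimals on the BCV scale and
recovery tests bound any systematic offset (φ = 0.04, 6 samples → BCV
0.20 ± 0.02). The search upper bound (φ ≈ 5) comfortably covers BCVs seen
in real pseudo-bulk cohorts (≈ 0.15–0.5).

## Simulator

Per sample (subject): per-cell expected library sizes are log-normal
(default meanlog 7.5, sdlog 0.35 — median ≈ 1,800 UMI, a typical 10x
yield; both configurable). Expected counts are baseline proportions ×
library size, with each group's spiked genes multiplied by 2^log2FC and
the vector renormalized (the renormalization perturbs non-spiked genes by
< 0.5% at the default 50 × 4 spiked genes). Baseline proportions are
either user-supplied or a seeded heavy-tailed synthetic spectrum
(log-normal intensities, meanlog −1, sdlog 2, normalized; spans > 4 orders
of magnitude like real UMI profiles). Intra-subject dependence uses the
one-factor equicorrelated construction z_gc = √ρ·a_g + √(1−ρ)·b_gc (exactly
the equicorrelated MVN, O(K) per gene); u = Φ(z) is clipped to
[10⁻¹², 1−10⁻¹²] and pushed through the Gamma(1/φ_sc, scale μφ_sc)
quantile, and counts are Poisson around the gamma variates. Marginals are
NB with variance μ + φ_sc μ²; the correlation affects only the biological
(gamma) layer.

Numerical choice: the gamma quantile is evaluated through a per-shape
monotone interpolation table (8,193-point z-grid over |z| ≤ 8.6, linear
interpolation of the log quantile), validated against the exact
regularized-incomplete-gamma inverse to max relative error < 10⁻⁵ — two
orders of magnitude below the NB sampling noise at any benchmark size, and
roughly 100× faster, which is what makes replicated benchmarks cheap.

Scenario presets solve φ_sc from the aggregation relation
φ_agg = ρφ_sc + (1−ρ)/N at the 250-cell baseline (scenario 4 also solves
at the baseline; with unequal cell counts the per-sample φ_agg then spreads
by ≈ ±0.002 around the target within a group). **The relation is
approximate by design**: for the gamma-Poisson model the independent
biological term is (1−ρ)φ_sc/N rather than (1−ρ)/N, and the Gaussian
copula attenuates the gamma-scale Pearson correlation a few percent below
ρ at the shapes used here. Consequently realized pseudo-bulk dispersions
sit 12–14% below the solved-for targets (e.g. scenario 1 realizes mean
estimated BCVs ≈ 0.187/0.206/0.242/0.260 against targets
0.20/0.22/0.26/0.28); the tests treat the relation as the definition of
the presets and separately verify the end-to-end aggregation consistency
at 15% tolerance. What the simulator does **not** model: batch effects,
zero inflation beyond NB sparsity, doublets, cell-type misassignment, or
outlier samples — conclusions from passing benchmarks transfer to real
data only to the extent those artifacts are absent or handled upstream.

## Benchmark harness

Per replicate: simulate, aggregate, filter (< 30 reads), TMM; fit each
method once on the full 4-group means-coded design and test all 6 pairwise
contrasts (pooling residual information across groups — precisely the
mechanism that makes the pooled-variance methods mis-calibrated under
heteroscedasticity); call DE at BH-adjusted p ∈ {0.01, 0.05, 0.10};
score FDR = FP/max(#called, 1) and TPR = TP/100 against the disjoint
truth sets. A comparison with zero calls contributes FDR 0. Replicate r
uses seed + r, so a (seed, reps) pair is fully reproducible. Default
reps = 50 mirrors the full study; the bundled checks use 10–20 replicates,
which keeps each scenario's summary within a few minutes at 10,000 genes
while widening Monte-Carlo error on mean FDR to roughly ±0.01.

## Degenerate inputs and tie-breaks

Zero-cell samples, all-zero samples (TMM), saturated designs, zero
contrasts, and infeasible BCV targets all raise informative errors rather
than propagating NaNs. Deterministic tie-breaks: TMM reference (lowest
index), result tables (stable sort by p then gene ID), group level order
(first appearance). All estimators are deterministic given their inputs;
the only randomness in the package lives in the simulator and is seeded.
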