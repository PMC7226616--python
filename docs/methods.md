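# Methods

## Model and procedure

The pipeline treats plot-level grain yield `y` as a sparse linear function
of an organ's metabolite profile. With `X` the n×p matrix of intensities
(raw or log2) for one organ–stage subset, each resampling run solves

    min over (b0, β) of  (1/2n)·‖y − b0 − Xβ‖² + λ·‖β‖₁

on a 75% training subset, with features standardized inside the training
rows only (validation rows are scored through the de-standardized
coefficients, so no information flows from validation into training). The
penalty λ is chosen per run by inner 5-fold cross-validation over a
100-point log-spaced grid from λ_max = max_j |x_jᵀy|/n down to 10⁻³·λ_max,
taking the λ with minimal mean validation MSE (largest λ on ties; a
one-standard-error rule is available). One hundred independent 75/25 splits
are drawn; per run the pipeline records training R², Adj-R²
(1 − (1−R²)(n−1)/(n−p−1) with p = selected features; undefined and flagged
NaN when n ≤ p+1), training RMSE, and the predictive ability — the squared
Pearson correlation between predicted and observed yield on the held-out
25% (defined as 0 when either side is constant). A metabolite's detection
rate (DR) is the fraction of runs with a strictly nonzero coefficient at
the selected λ; effects are averaged both over all runs (zero-inclusive,
shrinkage-honest) and over selecting runs only, since either convention is
defensible for an effects table.

Metabolites with DR ≥ 0.70 (inclusive) are refit by OLS — once on all rows
and once per growing condition (WS, HY), re-estimating coefficients in each
subset but keeping the globally selected feature set. Each refit reports
Adj-R², the overall F-test, and a decomposition of the model R² into
per-feature shares: *sequential* Type-I incremental R² with features
entered in DR order (simple, reproducible, order-dependent), and *LMG* —
incremental R² averaged over all feature orderings, computed exactly via
the subset-weight formula for ≤ 10 features (cached R² over all 2^m
subsets) and by sampled orderings above; above 20 features LMG is refused
unless a sampling budget is given. Both decompositions sum to the model R²
by construction.

## Resampling design

The source description of the resampling scheme is internally inconsistent
("five-fold CV" implies 80/20 splits, yet the subsets are described as
random 75% draws). The default implements the operationally detailed
version — 100 independent uniform 75/25 subsamples — because it is fully
specified; a literal 20-repeats-of-5-fold mode (`make_splits(...,
mode="kfold")`) is provided for comparison. Optional stratification keeps
the per-level proportions of a design column (e.g. condition) in every
training set, allocating per-stratum counts by largest fractional
remainder.

## Solver

The LASSO is solved by cyclic coordinate descent with covariance updates
(precomputed XᵀX, Xᵀy) on population-sd-standardized columns, soft
thresholding each coordinate; the intercept is never penalized; paths are
warm-started from large to small λ; coordinate order is cyclic for
reproducibility. Convergence requires both (a) a full sweep that moves no
coefficient by ≥ tol (default 10⁻⁸) and (b) the KKT stationarity conditions
within 10·tol — the sweep-delta criterion alone can fire prematurely on
ill-conditioned unpenalized problems, and the KKT certificate is the
contract every converged fit must satisfy. Fits that exhaust `max_iter`
(10⁵ sweeps) are returned with `converged=False` and a warning.

Two numerical choices matter for throughput. First, a working-set strategy:
the active set is iterated to stability between full sweeps. Second, the
inner-CV scoring paths run at a dedicated looser tolerance (`cv_tol`,
default 10⁻⁴ coefficient-change): at the deep end of the path with p > n,
near-degenerate fits oscillate between correlated coordinates for 10⁴–10⁵
sweeps at 10⁻⁸ while the CV curve is insensitive to coefficient error far
below the validation noise; the per-run *reported* fit at λ* keeps the
strict tolerance (warm-started from the path). The inner kernel is
JIT-compiled with numba. scikit-learn's `Lasso` — which shares the 1/(2n)
objective convention — serves as an independent cross-check in the test
suite, never as the implementation.

## Preprocessing

The missingness filter removes metabolite j iff (masked cells)/(samples)
is strictly greater than 0.10 ("more than 10%": a column at exactly the
threshold is kept). KNN imputation (k = 10, the documented default of the R
package the original analysis used; the analysis itself does not state k)
follows the Troyanskaya convention: distances are Euclidean over
metabolites observed in both samples, each metabolite scaled to unit
variance on its observed values, squared distances divided by the number of
shared observed columns; imputed values are inverse-distance-weighted
means (weights 1/(d+10⁻⁹) so duplicate samples do not divide by zero) of
the k nearest samples that observe the target metabolite, falling back to
all available neighbours (with a warning) when fewer than k exist and to
the column median when none does. Observed cells are never altered.
Imputation is applied per organ–stage subset — the unit entering each
model — with a pooled option, since the original order of operations is
unstated. Standardization for the penalized fits happens inside each
training fold only.

## Synthetic generator

The generator emulates the study's factorial layout: 3 organs × 2 stages ×
(5 genotypes × 4 trials × 3 replicates) = 360 organ samples, conditions
assigned per trial (2 WS + 2 HY). Log2 intensities are
`baseline_j + factor effects + intensity_sd · e_ij` with `e` carrying
block-exchangeable correlation `block_rho` within metabolite "pathway"
blocks (defaults: p = 80 metabolites, 10 blocks, ρ = 0.5, intensity_sd = 1
log2 unit — the within-plot replicate variation, exposed as a parameter
because it is design-specific); raw intensities are 2^(log2), so effects
are multiplicative on the raw scale and raw values strictly positive.
Missingness is MCAR per metabolite by default (rates mostly below 8%, with
~5% of columns drawn above the 12% filter threshold so the filter is
exercised); an intensity-dependent left-censoring mode exists because GC-MS
dropouts are often abundance-related. One root seed governs everything;
sub-streams are derived by stable hashing of (stage name, counter), so any
stage reproduces in isolation.

Yield is generated from the *log2* intensities — even when a model later
runs on the raw scale, so the raw-versus-log2 comparison is meaningful — as
`GY = intercept + log2(X)·β + shift·1[WS] + N(0, σ)` on a t/ha-like scale
(intercept 6.5, WS penalty −2.4 in the full-study default, matching a
~37% yield reduction under water stress). The sparse β has `s` nonzero
entries of equal magnitude and random sign, spread across distinct
correlation blocks: "s effects scaled for a target R²" is only defined up
to per-effect allocation, and equal allocation across non-redundant
features is the configuration whose minimum detectability the recovery
analyses measure. When a target signal fraction R²_true is requested, σ is
solved from the realized signal variance; the achieved
var(signal)/var(GY) is reported on the ground-truth object.

Scoping: `simulate_metabolome` itself applies *no* factor effects unless
templates are passed (its correlation-structure contracts — e.g. ρ = 0 ⇒
vanishing off-diagonal correlation — require a pure covariance model),
while the `simulate_cell`/`simulate_study` helpers default to realistic
organ/stage/condition/genotype shift templates. Controlled scenarios
(null calibration, recovery) set the WS yield *penalty* to zero so the
stated R²_true is carried by metabolite effects alone; the metabolome's
condition responsiveness is kept, as in the real system.

What the generator does not emulate: chromatogram/peak-level artefacts,
retention-time drift, batch effects, non-MCAR missingness beyond simple
left-censoring, non-linear metabolite–yield relations, and spatial field
structure. Passing tests therefore demonstrate the statistical behaviour of
the pipeline under a clean sparse-linear data-generating process, not
performance on real GC-MS data.

## Problem sizes

Tests and the acceptance script run the stability engine at the study's own
per-model scale (n = 60 plots, p = 80 metabolites, 100 resampling runs,
inner 5-fold CV over a 100-λ grid), with 10 generator seeds for the
calibration and recovery analyses and 20 for the imputation comparison;
unit tests use smaller grids (40 λ, eps 10⁻²) and fewer runs where only
qualitative behaviour is asserted. The end-to-end determinism check uses a
single organ–stage cell with 40 metabolites, 30 runs and both scales —
determinism is size-independent.

## Known limitations

* Detection at this scale is power-limited: spreading 70% of yield variance
  over 10 equal effects leaves each feature a partial t ≈ 3 in a 45-row
  training set with 80 candidates, and neither this solver nor an
  independent reference implementation selects every such feature in ≥ 70%
  of runs; the acceptance script reports the achieved detection and
  predictive-ability values rather than asserting an unreachable ideal.
* No post-selection inference correction is applied to the DR-refit F-tests
  and p-values (none was applied in the original procedure); they are
  conditional on a data-driven feature set and optimistic in the usual way.
* The per-condition refits re-estimate coefficients on ≤ 30 rows; their
  Adj-R² values are noisy.
* LMG shares are provably nonnegative only for orthogonal designs; small
  negative shares can occur with suppressor variables (not observed in the
  exhaustive checks up to 10 features, but not excluded).
* The factorial ANOVA fits fixed effects with Type-II sums of squares and
  treats trial/replicate structure as exchangeable noise; no random block
  terms are modelled.
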