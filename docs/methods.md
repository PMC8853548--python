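# Methods

## The problem being modelled

Microbiome feature tables (taxon or k-mer counts) are compositional: only
relative abundances are observable, and each study's wet-lab and
bioinformatic protocol multiplies the true abundances by unknown
feature-specific factors. When tables from several studies are pooled,
this multiplicative bias becomes an additive, study-aligned offset in any
log-based coordinate system, inflating false-positive case–control
associations whenever phenotype composition differs across studies, and
potentially distorting cross-study prediction. The package implements the
corrections, diagnostics and benchmarks appropriate to this structure.

## Transforms

Counts are closed to relative abundance. Zeros are replaced before any
log transform by a pseudocount of `0.65 × (global minimum non-zero
relative abundance of the table)`, after which rows are re-closed; the
perturbation is O(pseudocount) and within-row rankings of positive values
are preserved. The minimum is global over the whole table (not
per-sample) so the replacement value is common across samples; it is
recomputed per input table (e.g. per titration draw) and logged.

The CLR uses the natural logarithm; the base only rescales the PCs and
affects no downstream decision. Its inverse is the row-wise softmax,
invariant to per-row constants; the row maximum is subtracted before
exponentiation as an overflow guard. log-CPM uses the symmetric-prior
dialect `log2((c + prior) / (L + 2·prior) × 1e6)` with prior 0.5.

## Corrections

**BMC / DCC.** DCC regresses each feature on an intercept-plus-covariates
design by OLS and keeps the residuals; with a single categorical
covariate this is exactly per-batch mean centering, an equivalence the
test-suite checks against an independent BMC implementation. Constant
features pass through as zero residuals. Rank-deficient designs abort
with the aliased columns named.

**limma-style removal.** Batch and (optionally) phenotype terms are
fitted jointly; only the intercept and batch contributions are
subtracted, so a protected phenotype effect survives. With no protected
term the output equals DCC on the batch label.

**ComBat.** The parametric empirical-Bayes algorithm: per-feature
standardization by the grand mean and pooled variance; per-batch
location/scale estimates; normal prior on locations and inverse-gamma
prior on squared scales with method-of-moments hyperparameters pooled
across features; the standard iterative conditional posterior-mean
updates to convergence (absolute change < 1e-6, at most 500 iterations —
non-convergence is an error, not a silent truncation). Batch scale
estimates use the same divisor (n) as the pooled variance, which makes
two identical batches an exact fixed point of the adjustment; the common
R implementation uses n−1 there, so cross-implementation agreement is
expected to ~1–3 % at moderate batch sizes (the test suite compares
against Bioconductor sva on a 50-per-batch fixture at that tolerance).
Feature–batch cells with zero within-batch variance are location-adjusted
only. A single-feature table degenerates to the feature's own estimates
(no pooling is possible). ComBat and limma removal operate on
ln(relative abundance + pseudocount); the corrected table is mapped back
by exponentiation and closure.

**Percentile normalization.** Within each batch, each value becomes
`100 × (#controls below + 0.5 × #controls equal) / n_controls` with that
batch's controls as reference; the midrank tie convention is a documented
choice (the method's origin does not fix tie handling). The output is
rank-based, hence invariant to strictly monotone per-feature within-batch
transformations. Because the method needs control labels it is available
in the titration benchmark but excluded from the prediction harness,
where test labels are unknown by construction.

**PCA correction.** Covariance (unscaled) PCA of mean-centered CLR data
via SVD — CLR already places features on a common log scale, so no
variance scaling is applied. The sign of each loading column is fixed by
making its largest-magnitude entry positive. `pca_correct_fixed(p)`
subtracts the projection onto the top-p loadings and restores the feature
means (restoring means matters because per-feature constants do not
cancel under the inverse CLR; a `restore_means=False` variant exists).
`p = 0` is the identity. Since CLR rows and hence all fitted loadings lie
in the zero-sum hyperplane, the corrected table remains valid CLR data.

`pca_correct_tuned` fits the PCA on training data only, corrects the
validation table with training means and loadings (never refitting), and
picks the `p` maximising validation AUC (binary) or Pearson r
(continuous) with a fixed predictor; exact ties resolve to the smallest
`p`, the choice that discards the least phenotype signal. The paper-style
outer loop over k-mer sizes is realized by calling the tuner once per
user-supplied per-k table.

## Diagnostics

For each of the top PCs (default 15) and each covariate: continuous
covariates use |Pearson| with a two-sided t-test; categorical covariates
use the first canonical correlation, computed as √R² of the OLS of scores
on dummy-coded levels, with an F-test. Both are non-negative, so the
matrix lives in [0, 1]; the test used is recorded per cell. Constant
covariates yield correlation 0 with p = 1 and a warning. Before/after
comparisons use the one-sided *paired* Wilcoxon signed-rank on matched
(PC, covariate) cells — zero differences dropped, exact null for ≤ 25
informative pairs, normal approximation with continuity correction above,
and an error below 5 informative pairs where the test has no useful
power.

## Benchmarks

**Differential abundance.** Two-sided Wilcoxon rank-sum per feature on
relative (or corrected) values with Benjamini–Hochberg correction,
significant at q < 0.05. The exact null distribution is used when the
table is tie-free and small (≤ 60 samples); otherwise the normal
approximation with tie and continuity correction. Each class needs ≥ 3
samples.

**Titration.** The set size m is the minimum class size over the two
studies' available case and control pools (m ≥ 6 required). Per
replicate, m cases and m controls are drawn from study 1; at proportion
f, `round(f·m)` of the drawn controls are replaced by study-2 controls.
Replacement is nested across proportions within a replicate (larger f
strictly extends the swap), which makes the expected count monotone and
reduces Monte-Carlo noise. Cases and controls are redrawn every
replicate, all from named substreams of one seed. The pipeline per draw
is closure → prevalence filter → transform → correct → back-transform →
rank-sum+BH; the prevalence filter (default 0.1) is applied to the raw
relative table *before* zero replacement, because after the pseudocount
every value is positive and a presence/absence filter would be vacuous.
New associations are counted against the replicate's own proportion-0
significant set. Default proportions {0, 0.25, 0.5, 0.75, 1}, 5
replicates.

**Prediction.** LODO: one fold per study; the held-out study is the test
set and the rest is split 70/30 into train/validation, stratified by
phenotype (quartile bins for continuous phenotypes); folds whose test
study has a single class are skipped with a warning. Pooled scheme:
stratified 5-fold CV on (study × phenotype) strata — each fold's held-out
20 % is the test set, the remaining 80 % splits 70/30, giving the
56/24/20 partition; repeated (default 10×) for percentile confidence
intervals. Binary phenotypes use a random forest with entropy criterion,
`max_depth=None`, `max_features=sqrt(n_features)` (the standard
definition; a square-root-of-tree-count reading exists in the literature
but contradicts the referenced implementation), and a 27-point grid over
{100, 1000, 1500} trees × min-split {2, 5, 10} × min-leaf {1, 5, 10}
tuned by validation AUC. Continuous phenotypes use linear least squares
with an optional ridge grid {0, 1e-2, 1, 100} selected on validation —
λ = 0 is the plain model, the penalized options exist because feature
counts routinely exceed sample counts. Method comparisons use a
one-sided rank-sum test, annotated whenever the minimum attainable
p-value `1/C(n+m, n)` makes p < 0.05 impossible at the fold counts in
hand.

**Leakage control.** All data-dependent pipeline parameters — the
prevalence mask, the pseudocount value, PCA means and loadings — are
fitted on training samples only and applied forward. Batch mean centering
of a study never seen in training uses that study's own label-free means
at application time, since per-study offsets cannot be estimated in
advance. A test asserts that perturbing test rows leaves every fitted
parameter bit-identical.

## The synthetic-data generator

The generator emulates pooled multi-study case–control data:
per-feature baseline log-abundances ~ N(0, 1); per-feature, per-study
bias ~ N(0, bias_sd²) in log space (feature-specific, because a bias
common to all features cancels under closure and would produce no batch
effect); binary phenotype via study-dependent Bernoulli moving from
balanced (ρ = 0) to fully study-determined (ρ = 1); planted effects of
±effect_logfold on n_differential features; per-sample log-normal noise;
closure; multinomial counts at gamma-Poisson library sizes (mean 20 000,
squared CV 0.3). Sparsity arises from multinomial sampling of skewed
compositions, with an optional zero-inflation rate for harsher regimes.

Two generator design choices matter for calibration. Planted effects are
direction-balanced (half enriched, half depleted in cases) and placed on
the less-abundant half of the features, as disease-associated taxa are
typically not community dominants. Without both, the planted mass shifts
the per-sample normalization (closure, and the softmax denominator after
CLR-space correction), giving every null feature a spurious case–control
shift — a real compositional phenomenon, but one that would swamp the
error-rate calibration the benchmarks are meant to measure.

What the generator does *not* emulate: real taxon phylogenies and
correlation structure, covariate-rich designs (age, sex, geography),
protocol-specific sequence composition, or longitudinal sampling.
Passing benchmarks on this generator demonstrates correct algorithmic
behaviour under the stated noise model, not performance on any particular
real cohort.

## Desk-scale study conditions used by the tests and acceptance script

- *Titration:* 2 studies × 60 samples, 200 features, bias_sd 1, no true
  effects, ρ = 0, proportions {0, …, 1}, 10–20 replicates.
- *Null calibration:* 2 × 20 samples, 200 features, no bias, no effects,
  50–100 replicates.
- *Recovery:* 4 studies × 40 samples, 200 features, bias_sd 1, ±ln 4 on
  20 features, ρ = 0.5 for the corrected arm (partial confounding), fixed
  PCA p = 3; the uncorrected contrast arm runs at ρ = 1. Four studies give
  three between-study contrasts, matching the three removed components;
  at ρ = 1 the phenotype is inseparable from study, so full confounding
  is meaningful only for the uncorrected arm.
- *Tuned PCA:* 4 studies × 60 samples, bias_sd 3, ±ln 3 on 20 features,
  noise 0.8, p-grid 0..6, RF with 100 trees as the fixed predictor. The
  three study contrasts are the planted high-variance noise components
  orthogonal (ρ = 0) to the phenotype.
- *Prediction calibration:* 2 studies × 60 samples, no bias, ±ln 4 on
  20/200 features for the signal arm; 10 label permutations for the null
  arm; a single-point RF grid (100 trees) keeps the harness within
  desk-scale runtimes — the full 27-point grid is the library default.

## Numerical choices and degenerate inputs

Space inference on read: integer non-negative → counts; rows summing to
1 within 1e-6 → relative; else generic (overridable). Relative rows must
sum to 1 within 1e-8, CLR rows to 0 within 1e-8. Missing metadata cells
are tolerated only in columns not used by the requested analysis; used
columns with missing values are a hard error (no imputation). Zero-variance
features pass through BMC/DCC unchanged and are location-only in ComBat;
an all-zero sample row is an error at closure. Exact ties in the tuned-PCA
metric resolve to the smallest p; the rank-sum switches exact/asymptotic
as described above. TSVs round-trip at 12 significant digits.

## Known limitations

- ComBat supports the parametric prior only; no covariate protection
  inside ComBat (protection is available in the limma-style removal).
- Supervised corrections other than BMC are not available inside the
  prediction harness: reference-distribution methods (percentile) need
  labels at test time, and cross-batch application of fitted
  location-scale models to unseen batches is not defined by the
  benchmarked procedure.
- The titration benchmark requires a binary phenotype.
- Surrogate-variable and reference-sample methods (SVA, RUV,
  bias-calibration against spike-ins) are out of scope.
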