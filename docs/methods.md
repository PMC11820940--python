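# Methods

## The selection problem

A breeding program observes adjusted line means (BLUEs) y₁…yₙ for n
genotyped lines and must decide which lines belong to the top τ-fraction
(default τ = 0.8 quantile, i.e. the best 20%). A line is a *top line* when
its observed value strictly exceeds Yτ, the empirical τ-quantile
(linear-interpolation, type-7) of the training responses; ties at the
threshold are classified as not-top, since all decision rules here use
strict inequalities. Bottom-line selection (`direction="bottom"`, for
traits such as disease scores where low is good) mirrors every rule at the
1−τ quantile with reversed inequalities, keeping reported thresholds on
the trait scale instead of negating the response.

## Genomic relationship matrix

`grm.compute_grm` implements VanRaden's first method: with dosage matrix M
(n × p, codes 0/1/2), observed allele frequencies pⱼ = mean(Mⱼ)/2, and
W = M − 2P,

    G = W W′ / (2 Σⱼ pⱼ (1 − pⱼ)),

where monomorphic markers center to zero and are dropped from the
denominator sum. Frequencies are estimated from all lines, training and
test together, so a single G serves a whole dataset. Missing dosages are
mean-imputed per marker before G is built (raw files round-trip with their
missing codes intact). Because finite marker panels and duplicated lines
frequently make G numerically singular, `grm.stabilize` adds a ridge
(default 1e-6) to the diagonal before any decomposition; fits refuse a G
whose training-block minimum eigenvalue is below −1e-8 and point the user
to `stabilize`.

## GBLUP Gibbs sampler

Model: yᵢ = μ + gᵢ + εᵢ with g ~ N(0, σ²_g G) and ε ~ N(0, σ²I); flat prior
on μ; scaled-inverse-χ² priors on both variance components with df = 5 and
scales placing the prior mode at half the training-sample variance of y
(the genetic scale additionally divided by mean diag(G) so the split refers
to phenotypic variance).

The sampler is collapsed onto the training block. Writing
G_tt = U D U′ for the eigendecomposition of the training submatrix and
b = U′ g_train, the rotated effects have prior b ~ N(0, σ²_g D) and — since
U is orthogonal on that block — a fully diagonal conditional posterior:

    bⱼ | · ~ N( (tⱼ/σ²) / κⱼ , 1/κⱼ ),   κⱼ = 1/σ² + 1/(σ²_g dⱼ),

with t = U′(y_train − μ). All per-iteration quantities (t, the residual sum
of squares, Σ bⱼ²/dⱼ, 1′Ub) reduce to O(n) vector operations after
precomputing U′y and U′1, so a 6000-iteration chain on n = 300 runs in well
under a second. Eigenvalues below 1e-12 of the largest are dropped
(pseudo-inverse convention); the corresponding effect components are fixed
at zero.

Masked (test) lines contribute no likelihood and are predicted through the
conditional mean E[g_test | g_train] = G_st G_tt⁻¹ g_train = (G_st U D⁻¹) b,
accumulated as a posterior mean. This yields the same posterior over g as a
full-vector or response-imputation parameterization, with less machinery to
verify. Defaults: n_iter = 6000, burn_in = 1000, thin = 5 — generous for the
fast-mixing small-n GBLUP; the seed is mandatory everywhere, never
defaulted. Identical settings and inputs give bit-identical chains.

For testing, `fit()` accepts fixed variance components and a fixed
intercept, in which case the posterior mean must agree with the
deterministic `blup_closed_form`
(ĝ = σ²_g G·,t (σ²_g G_tt + σ²I)⁻¹ (y_t − ȳ_t)); the estimation minimum of
20 training lines is waived there since nothing is estimated beyond the
Gaussian effects.

## Probit threshold model

Binary labels enter through a latent liability lᵢ = β₀ + gᵢ + εᵢ with the
residual liability variance fixed at 1 (it is not identifiable) and a flat
prior on β₀. Liabilities are drawn from truncated normals (positive iff the
label is 1) by inverse-CDF sampling; given l the update is the Gaussian
machinery above with σ² = 1. Predicted probabilities for masked lines are
posterior means of Φ(β₀ + gᵢ) where g_test is *sampled* each kept iteration
from its conditional normal (mean A b, covariance σ²_g(G_ss − G_st G_tt⁻¹
G_ts), Cholesky with 1e-8 jitter) — averaging Φ over draws rather than
applying Φ to the posterior mean, since Φ is nonlinear. In-sample fitted
probabilities are accumulated the same way. Final probabilities are clipped
to (1e-12, 1 − 1e-12) so downstream strict comparisons are well defined.
Training labels must contain both classes; otherwise the truncation is
degenerate and the fit refuses.

## Threshold optimization

For RO and BO the base rule is replaced by the cutoff minimizing
(Sensitivity − Specificity)² on inner validation folds:

* candidates on the trait scale are the midpoints of consecutive sorted
  validation scores plus one candidate below the minimum and one above the
  maximum — this enumerates every achievable confusion matrix, which a
  fixed grid would not;
* on the probability scale, the midpoints of sorted unique probabilities
  plus 0.5 itself, so the optimized objective can never be worse than the
  fixed-half rule's on the same folds;
* ties in the objective go to the candidate closest to the base threshold
  (Yτ or 0.5), then to the smaller candidate — minimal deviation from the
  default rule, deterministic;
* single-class validation folds are skipped; if every fold is degenerate
  the base rule is returned with a `DegenerateFoldsWarning`;
* the final threshold is the mean of the per-fold optima, retained in
  `ThresholdRule.fold_values`.

The per-fold optimum never exceeds the base rule's objective on that fold
(the base cutoff's confusion matrix is always among the candidates); the
averaged threshold itself carries no such per-fold guarantee, which is why
the corresponding test checks the per-fold objectives.

`adjusted_predictions` exposes the equivalent reformulation
Ŷ* = Ŷ·(Yτ/Y₀): comparing Ŷ* to Yτ reproduces comparing Ŷ to Y₀ whenever
the two thresholds share a sign; with opposite signs the identity fails, a
warning is emitted, and the direct Y₀ comparison is authoritative.

**Original vs Simple.** Method O refits the model in each of the 10 inner
folds and scores the held-out validation lines out-of-sample. Method S fits
once on the full outer-training set, then partitions the *in-sample fitted
values* into 10 folds for the optimizer (`simple_tuning_scores`). The
once-fitted scores are less shrunken than out-of-sample predictions, so the
Simple threshold sits systematically slightly above the Original one; on
the standard synthetic design the mean discrepancy stays below a quarter of
the interquartile range of the responses. Tuning on test-set predictions
would leak test labels into the threshold and is deliberately not offered.

## Nested cross-validation

`run_nested_cv` operates on a single (environment, trait) slice — models
carry no environment term, matching per-environment analysis. Outer 5-fold
partition by seeded permutation; per fold: Yτ from the outer-training
responses only; GBLUP (RC/R/RO) or probit on Yτ-binarized training labels
(B/BO) with the test lines masked; threshold per scheme; confusion matrix
and metrics on the test lines. Inner partitions use seeds derived
deterministically from the plan seed per outer fold (independent of the
outer permutation). RC's rank-matching uses stable sorting, so ties at rank
k resolve by line order; its predicted- and observed-positive counts are
equal by construction, forcing FP = FN and hence Sensitivity = Precision.
Test responses influence nothing upstream of their own observed labels — a
dedicated audit corrupts them and asserts every threshold and every
prediction is bit-identical.

Aggregation is hierarchical: mean over folds per (environment, trait); mean
and SE (sd/√k across environment × trait combinations) per dataset; then an
unweighted mean of dataset summaries ("Across_Data"). Undefined metric
values (0/0 cells; κ when chance agreement is 1) are NaN-flagged, excluded
from means, and counted in `n_undefined` — coercing them to 0 would bias
dataset means. Relative efficiencies are reported as RE = y/z with percent
improvement (RE − 1)·100 or percent decrease (1 − y/z)·100, rounded to two
decimals.

## Synthetic data

The generator emulates the benchmark data shapes: dosages are
Binomial(2, p) per line with allele frequency p uniform on the MAF range
(0.05, 0.5) — Hardy–Weinberg proportions, no linkage disequilibrium, since
G captures realized relationships regardless of LD. Phenotypes are
y = μ + Wβ + e with standard-normal effects on a random QTL subset of the
(frequency-centered) markers, and residuals rescaled so the realized
in-sample variance ratio equals the target h² *exactly*, giving recovery
tests a sharp truth rather than an expectation. Traits and environments
receive independent effect draws (no G×E), matching per-environment model
fitting. Defaults (n = 300 lines, p = 500 SNPs, 50 QTL, h² = 0.5, τ = 0.8)
are the replicate design used throughout the tests; presets `tiny`
(60 × 200, seconds end-to-end) and `maize_shape` (1000 × 4085, 11
environments × 4 traits, mirroring the maize benchmark dimensions) write
ready-made CSV bundles.

What passing tests on these data do **not** show: robustness to LD
structure, population stratification, non-additive gene action, G×E, or
non-Gaussian residuals — all present in real trials and all outside the
generator.

## Problem sizes and numerical choices

* Recovery and balance experiments use n = 300, p = 500; oracle-equivalence
  checks n = 100; end-to-end structural tests the 60-line `tiny` preset.
* Chains in the experiment suite are short (hundreds of iterations):
  posterior means of this fast-mixing sampler stabilize quickly, and the
  balance comparisons average over 10–20 independent replicates, which
  dominates Monte-Carlo error. Scientific defaults remain 6000/1000/5.
* Ridge 1e-6 on G; eigenvalue floor −1e-8 for the PSD check; prediction
  pseudo-inverse cut at 1e-12 of the leading eigenvalue; probabilities
  clipped at 1e-12.
* ESS is Geyer's initial-positive-sequence estimator on the scalar chains.

## Known limitations

* Single-trait, single-environment models only; no multi-trait or G×E
  covariance structure, and no alternative marker-effect priors.
* The probit intercept's posterior mean shows the usual mild shrinkage
  toward zero at moderate n; the heritability posterior is likewise pulled
  slightly toward the 50/50 prior split at n = 300.
* The Simple variants tune on in-sample fitted values; their thresholds are
  biased upward relative to Original tuning (see above), the price of
  fitting once.
* `blup_closed_form` and the samplers materialize dense n × n matrices;
  the implementation targets breeding-panel sizes (hundreds to a few
  thousand lines), not biobank scale.
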