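# Methods

## Model and estimand

The design model assumes each subject's S pre-treatment and T post-treatment
measurements are jointly multivariate normal with an exchangeable-block
covariance: a single within-baseline correlation ρ_X, a single
within-follow-up correlation ρ_Y, and a single cross-period correlation
ρ_XY, with marginal variances σ²_X and σ²_Y. The analysis model is ANCOVA on
subject-level means: Ȳᵢⱼ = μ_i + β(X̄ᵢⱼ − X̄) + εᵢⱼ, and the estimand is the
difference in follow-up means between arms, δ.

The variance of δ̂ is computed from the block means of the covariance
matrix: var(δ̂) ≈ (1/n₀+1/n₁)(Σ̄_post − Σ̄²_pre-post/Σ̄_pre), where each Σ̄ is
the arithmetic mean of all elements of the corresponding block. This is the
large-sample approximation that drops the (n₀+n₁−2)/(n₀+n₁−3) factor and the
randomization-negligible between-arm baseline imbalance term; the 20,000
replicate check in the test suite confirms the approximation is within 5% of
the empirical variance at n = 50 per group. Under the exchangeable-block
structure the block means have closed forms, giving the variance bracket

    (1+(T−1)ρ_Y)/T − ρ²_XY·S/(1+(S−1)ρ_X),

which also drives the sample-size formula and everything in the allocation
optimizer. `variance_general` accepts any user-supplied covariance matrix,
so non-exchangeable structures can be explored numerically even though no
closed-form optimizer is provided for them.

### Validity region and rounding

The three-correlation parameterization is not automatically a valid
covariance for every (S, T): before any computation the implied
(S+T)×(S+T) matrix is built and its smallest eigenvalue checked against
−1e−10. ρ_X = 0 and ρ_XY = 0 are allowed in the design formulas (the
bracket remains well defined) even though the allocation theory excludes
them.

Per-group sample sizes use standard normal quantiles and are rounded **up**
(ceiling); the unrounded value is always exposed, and ratios of sample sizes
are always ratios of unrounded values. Ceiling is adopted because it is the
conservative convention and reproduces every entry of the worked example's
published table (e.g. 45.88 → 46, 32.82 → 33).

## Visit allocation

For fixed M = S+T, minimizing sample size is minimizing
f(S) = (1+ρ_Y(M−S−1))/(M−S) − ρ²_XY·S/(1+ρ_X(S−1)) over S ∈ [1, M−1].
Under 0 < ρ_X, ρ_Y < 1, ρ_XY ≠ 0 and ρ_Xρ_Y ≥ ρ²_XY, f has a unique interior
minimum when M exceeds √((1−ρ_Y)/((1−ρ_X)ρ²_XY)) + 1, else S = 1 is optimal.

The stationary point is evaluated in the square-root form
s₀ = [M√(Bρ_X) − √A(1−ρ_X)] / [√(Bρ_X) + √A·ρ_X] with A = 1−ρ_Y and
B = ρ²_XY(1−ρ_X)/ρ_X. This is algebraically identical to the rationalized
quotient form but its denominator is strictly positive, so no degenerate
branch is needed. Integer rounding compares f at ⌊s₀⌋ and ⌈s₀⌉ (clipped to
[1, M−1]); ties go to the smaller S — fewer baselines at equal efficiency,
since follow-ups carry the outcome. Every integer answer is verified against
exhaustive search over [1, M−1]; when the closed-form assumptions fail
(e.g. ρ_Xρ_Y < ρ²_XY with a still-PSD matrix) the optimizer warns and uses
exhaustive search directly, since uniqueness is only guaranteed under the
assumptions.

## Synthetic data

The continuous generator draws from the multivariate normal with the
exchangeable-block covariance (unit variances by default, matching the
simulation-study convention), mean 0 everywhere except the treated arm's
follow-ups, which are shifted by δ.

The binary generator is a Gaussian copula: latent normals with correlation
matrix R (ρ_X/ρ_Y/ρ_XY pattern, unit diagonal) are mapped through Φ to
uniforms and dichotomized at p (control arm everywhere; treated arm uses p
for baselines and p′ = p·e^{β₁}/(1−p+p·e^{β₁}) for follow-ups, i.e. a β₁
log-odds shift). R lives on the **latent-normal scale**; the induced
correlations among the 0/1 variables are attenuated relative to R (a test
asserts this). The generators emulate balanced, complete data with
exchangeable dependence; they do not model missingness, visit-time
irregularity (e.g. autoregressive decay), or covariates beyond the baseline
outcome — conclusions from passing tests transfer to real trials only to
the extent those features are ignorable.

Replicate r of a Monte-Carlo run uses the r-th child of
`SeedSequence(root_seed)`, so runs are bit-reproducible and replicate
results are independent of execution order.

## Analysis models

* **ANCOVA** — three-parameter least squares solved in closed form
  (cross-checked against statsmodels OLS to machine precision in the tests);
  two-sided t test with n₀+n₁−3 degrees of freedom.
* **Logistic (T = 1)** — statsmodels `Logit` with treatment plus a baseline
  summary: the last baseline (model 1), the empirical logit
  log[(X+½)/(2−X+½)] of the summed two-baseline count (model 2), or the
  count as a categorical covariate with reference level 0 (model 3). For
  S = 2, model 2 is an affine recoding of the raw count, so its treatment
  test is identical to the linear-in-X model (asserted to 1e−10).
* **GEE logistic (T ≥ 2)** — statsmodels `GEE`, Binomial family, robust
  sandwich variance; covariate X₊ = ΣXₛ (model 1) or its empirical logit
  log[(X₊+½)/(S−X₊+½)] (model 2 — the denominator generalizes the printed
  two-baseline form to arbitrary S while reducing to it at S = 2). The
  working correlation is exchangeable by default with independence
  available; because all covariates are cluster-constant and clusters are
  balanced, the two give identical estimates here. With T = 1 the call
  dispatches to ordinary logistic regression on the same covariates.

Perfect separation or non-convergence is flagged (`separation=True`,
standard errors above 50 or non-finite are treated as diverged) rather than
raised; the Monte-Carlo engine drops flagged replicates from the rejection
denominator and reports the count. At 50 subjects per arm the categorical
model 3 is separation-prone, so simulation presets skip it at that size.

## Monte-Carlo engine and calibration

Rejection is p < α for uncalibrated tests. For the small-sample GEE Z test
the robust sandwich variance is biased downward, inflating |Z|; the engine
therefore supports empirical calibration: simulate the matching null
scenario, take the empirical α/2 and 1−α/2 quantiles of the Z statistics as
order statistics at rank ⌈q·N⌉ (inverse empirical CDF — this choice
guarantees the null rejection with these critical values does not exceed α),
and reject when Z falls outside them. Applying the critical values to their
own null stream rejects at exactly α up to order-statistic discreteness.
Power curves over S calibrate each split from its own independently seeded
null stream of the same size as the power run.

Default replicate counts: 20,000 for reproducing the published simulation
cells (Monte-Carlo SE ≈ 0.0015 at α = 0.05), 5,000 for the CLI's smoke mode,
and 2,000 per split for the calibrated GEE power curves, where each point
additionally inherits noise of roughly ±0.02 from the estimated quantiles —
per-point comparisons along a curve should be read with that in mind.

## Known limitations

* The allocation theory covers the exchangeable-block structure only;
  autoregressive or unequally spaced designs are supported only through
  `variance_general` with an explicit matrix.
* Equal per-group allocation is assumed in the sample-size formula.
* No missing-data handling, interim re-estimation, or cost-constrained
  optimization.
* Calibrated GEE power comparisons carry quantile-estimation noise in
  addition to binomial error; increase replicates when ranking near-tied
  splits.
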