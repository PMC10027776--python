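# Methods

## Measurement model and estimation

All factor models are simple-structure: each item loads on exactly one
factor, errors are mutually uncorrelated and uncorrelated with the factors,
factor variances are fixed at 1 and factor covariances are free. The
implied covariance is `Sigma = Lambda Phi Lambda' + Theta`. Constraint
levels mirror the CTT taxonomy: congeneric (free loadings and unique
variances), tau-equivalent (equal loadings within a factor block), parallel
(equal loadings and equal unique variances). A mean structure is fitted
only when sample means are supplied; the `strict_means` flag adds
equal-intercept constraints within blocks, otherwise the "essentially"
variants are estimated. With three indicators and one factor the model is
just identified and the closed form `lambda_1 = sqrt(c12*c13/c23)`
(cyclically) reproduces the covariances exactly; it doubles as an
independent oracle for the ML optimizer in the tests.

Estimation minimizes the normal-theory discrepancy
`F_ML = ln|Sigma| + tr(S Sigma^-1) − ln|S| − p` (plus
`(xbar − nu)' Sigma^-1 (xbar − nu)` when means are modeled) with analytic
gradients under L-BFGS-B. Unique variances are parameterized on the log
scale with a floor of 1e−6; an estimate at the floor is flagged as a
Heywood case on the result, never silently truncated above it. Factor
correlations are atanh-parameterized. Start values come from block
covariance averages; up to 10 deterministically jittered restarts are
attempted before a convergence error (which carries the best state found)
is raised. Gradient tolerance is 1e−8. Factor orientation is fixed by
forcing the first loading of each block positive.

Degrees of freedom are `p(p+1)/2 (+ p with means) − free parameters`; on
six indicators the one-factor congeneric/tau-equivalent/parallel models
have df 9/14/19. The chi-square statistic uses the `(n−1)·F_ML` convention
(software dialects differ; one convention is fixed and documented here).
RMSEA is `sqrt(max(0, chi2 − df)/(df(n−1)))`, its 90% CI from
noncentral-chi-square inversion by bisection on the noncentrality parameter
at cumulative probabilities 0.95 and 0.05 (bisection tolerance 1e−6).
CFI/TLI use the independence (diagonal-Sigma) baseline, whose discrepancy
is `−ln|R|`. SRMR averages squared residuals standardized by the sample
SDs; the default includes the diagonal terms (which are nonzero because
implied variances need not match sample variances), with an
off-diagonal-only dialect behind a flag.

## Reliability coefficients

All estimators run on the raw-score (covariance) metric; correlation input
must be converted with supplied SDs, never silently. Alpha may be negative
for pathological inputs and is reported as computed. Omega_T requires a
single-factor solution; under exactly equal loadings it coincides with
alpha, under unequal loadings (and exact one-factor structure) it exceeds
alpha, and when a single factor under-explains the off-diagonal covariance
alpha can exceed omega_T — the test suite constructs all three regimes.
The determinacy quantities take loadings as input rather than refitting, so
population and plug-in sample behavior can be compared; a convenience
wrapper (`reliability_report`) chains the fit. The correlation between
regression factor-score estimates and unit-weight sums is computed as
`1'lambda / sqrt(lambda'C^-1 lambda * 1'C1)`: the numerator is
`cov(lambda'C^-1 x, 1'x) = lambda'1` and the variances are
`lambda'C^-1 lambda` and `1'C1`. Coefficients are carried at full floating
precision; rounding to 3 decimals (4 for the near-unity correlation)
happens only at report rendering.

## Structural methods

Latent outcomes in the factor-score and simultaneous methods are
identified by fixing each factor's model-implied *total* variance to 1.
Consequences: the raw slope B is in latent-SD units (so d = B), beta =
B·SD(z) is the model-implied factor–predictor correlation, and the
Croon-corrected two-stage estimate and the simultaneous ML estimate target
the same quantity and can be compared directly. d always standardizes by
the outcome's total (sample or model-implied) SD — the convention that the
reference analyses' own arithmetic follows — not by a pooled within-group
SD. The predictor's SD uses the n−1 sample formula, including for binary
codes.

Method 3 (Croon) fits each block's congeneric model separately, forms
regression scoring weights `W = lambda' Sigma_hat^-1`, and corrects the
score moments back to the latent metric: `var(f) = (W S W' − W Theta W') /
(W Lambda)^2`, `cov(f, z) = W c_xz / (W Lambda)`. Its SEs and 95% CIs come
from a seeded nonparametric bootstrap over persons (default 499 resamples;
resamples with a degenerate predictor or failed fit are skipped and
counted). Method 4 fits items and z jointly by ML; z is an observed,
error-free single-indicator variable with variance fixed at its sample
value, structural slopes are sine-parameterized so the unit-total-variance
identification holds throughout optimization, and SEs come from the
inverse observed information ((n−1)/2 times the numerical Hessian of the
discrepancy) with a delta-method map to the reported slope. Estimation is
plain ML throughout; robust (sandwich) corrections are out of scope.
Significance is reported as estimate, SE and 95% CI — never as a star or
threshold.

## Synthetic data

The generator draws factors from MVN(0, Phi), adds independent normal
errors, and optionally discretizes each item onto 1..L by equal-probability
thresholds under the item's own marginal normal. This emulates Likert
response scales; it does not reproduce the skew, category imbalance, or
item-specific distortions of real questionnaire data, so passing tests
demonstrate correctness of the estimators under the stated model, not
robustness to real-world misfit. Criteria are generated at the factor
level (`r·f + sqrt(1−r^2)·noise`), making the configured r the exact true
validity and the attenuation identity (observed validity = true validity ×
sqrt(score reliability)) available in closed form for continuous items.

The split-sample harness (`crossval_validity`) generates one population
sample, repeatedly draws a calibration subsample (default 200 of 4000),
fits the one-factor model there, and scores the holdout with the
calibration weights and calibration means — deliberately reusing
calibration standardization, since that is what "scoring a new sample with
fixed weights" means in practice. One hundred replications run in a few
seconds. The default item pool is 14 items with loadings evenly spread
over .40–.70 in standardized metric (unique variances 1 − lambda²), a
6-point response scale, one criterion at true validity .40 and one null
criterion — a realistic broad-personality-scale regime in which sum scores
and factor-score estimates are expected to cross-validate equivalently.

The Wilks table evaluates the weighted/unit-weighted composite correlation
analytically per random positive (uniform 0–1) weight draw on an
exchangeable correlation matrix (default common r = 0.3), so its Monte
Carlo error comes only from the weight draws.

## Numerical and design choices

- Sample covariances use the n−1 denominator everywhere, as does item
  standardization in composite scoring.
- Composite scoring fails on missing cells among weighted items by
  default; per-person mean imputation is an explicit opt-in flag. Whether
  to standardize before summing is likewise an explicit flag with no
  default inference.
- Weights are taken as given; nothing is normalized silently.
- Covariance CSVs are symmetry-checked to 1e−8 and then symmetrized
  exactly; sample matrices must be positive definite (checked by
  eigenvalue).
- All stochastic operations require a seed and are bit-reproducible given
  (seed, config); skipped replications are reported, never imputed.
- Problem sizes in the test suite (e.g. n = 5000 for recovery checks,
  n = 20000–100000 for Monte Carlo identities, 100 replications for the
  cross-validation and coverage checks) were chosen so Monte Carlo error
  is comfortably inside the asserted tolerances while the whole suite runs
  in seconds.

## Known limitations

- No IRT scoring, bifactor/omega-hierarchical decompositions,
  modification indices, ordinal (WLSMV) estimation, or robust (MLR)
  corrections.
- Analytic SEs for the Croon two-stage estimator are not implemented
  (bootstrap instead).
- Exact reproduction of full-battery fit statistics and regression tables
  for the classic datasets requires the raw person-level data, which are
  not shipped; the toolkit reproduces all quantities computable from the
  printed covariance fixtures and validates the rest on synthetic data
  with known truth.
- The ML optimizer targets small-to-moderate p (tens of indicators); it is
  not tuned for very large item pools.
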