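# Methods

## Model

The package implements the bivariate latent curve model with structured
residuals (LCM-SR) for a two-burst measurement design. Observed scores
(here: a frailty index FI in [0, 1] and a loneliness sum score LS in
3–9, each at 14 biweekly waves in two bursts of 7 set a year apart) are
decomposed into a between-person growth part and a latent wave-specific
residual:

```
FI_it = RI^FI_i,b(t)                         + r^FI_it
LS_it = RI^LS_i,b(t) + c_t * S^LS_b(t)       + r^LS_it
```

- One random intercept per construct per burst (4 in total), with free
  means and variances and all 6 pairwise covariances (zeta). Observed
  intercepts are fixed to 0 whenever a random intercept carries the mean.
- Slope loadings are coded 0, 1, ..., 6 across the waves of a burst
  (time unit: one biweekly wave), so the burst intercept is the level at
  burst start. Any affine recoding of the loadings is likelihood-
  equivalent after compensating transformations of the growth-factor
  moments; this is verified numerically in the test suite. In the
  canonical model the loneliness slopes are *fixed*: free mean, zero
  variance.
- Each observed variable loads 1 on exactly one latent residual and has
  observed-level residual variance fixed to 0; all occasion-level
  variance lives in the latent residual. Residual (wave-1 marginal /
  innovation) variances are wave-specific and free — 28 in the bivariate
  model — with no stationarity constraint.
- Residual dynamics connect adjacent waves only: autoregressions
  (alpha for FI, beta for LS), cross-lags (gamma: FI→LS, delta: LS→FI),
  and a within-wave cross-construct residual covariance (lambda, 14).
  The burst gap (wave 7 → 8, one year) receives its own free lag
  coefficients of the same form, so there are 13 of each lagged
  parameter.

The canonical bivariate model has 110 free parameters; against the
434 saturated moments of 28 observed variables this gives 324 degrees of
freedom. This count is asserted without data in the tests.

## Estimation

Models are compiled to RAM matrices (A: directed paths, S: symmetric
covariances, M: means, F: observed filter); implied moments are
`mu = F(I-A)^-1 M` and `Sigma = F(I-A)^-1 S (I-A)^-T F^T`. The builders
only emit acyclic path diagrams, so `I - A` is always invertible.

The log-likelihood is full-information maximum likelihood under MAR:
persons are grouped by missingness pattern and each pattern contributes
through its count, mean and scatter — algebraically identical to the
person-by-person sum (tested to machine precision). A non-positive-
definite pattern submatrix yields a rejected point (log-likelihood
-inf), not an exception.

Scores are analytic. The derivative of the implied moments with respect
to a single matrix cell is a rank-one-plus-transpose update, so the full
gradient costs about as much as one likelihood evaluation; per-person
scores reuse the same terms. The observed information is obtained by
central finite differences of the analytic gradient with step
`1e-5 * (1 + |theta_j|)`.

Optimization details:

- Variances are log-parameterized internally; everything is reported on
  the natural scale.
- A diagonal preconditioner equalizes parameter scales: every variable
  is assigned its construct's pooled observed SD, an S-cell parameter
  scales as the product of its two variable SDs, a mean as one SD, a
  regression as the predictor/outcome SD ratio. Without this the frailty
  (variances ~0.003) and loneliness (means ~3.4) blocks differ by five
  orders of magnitude and quasi-Newton methods crawl.
- L-BFGS-B (bounded below in log-variance coordinates, floor 25 log
  units under the start) is followed by damped Newton polishing with an
  explicit finite-difference Hessian of the analytic gradient; Newton
  steps have floored eigenvalues and capped length so plateau directions
  (e.g. covariances of a slope whose variance sits on the zero boundary)
  cannot derail the line search.
- The objective is the mean per-person negative log-likelihood;
  convergence tolerances refer to that scale. A fit is flagged converged
  when the projected gradient falls below 100x the gradient tolerance
  (default tolerance 1e-5, so 1e-3 in the worst tier) or the optimizer
  reports relative-objective convergence with a projected gradient below
  1e-2. Non-converged fits are returned flagged, never silently.
- Starting values are deterministic: residual variances at half the
  observed variances, intercept means at burst-specific observed means,
  intercept variances at half the variance of person means, slope
  variances at a tenth of that, all dynamic parameters, covariances and
  slope means at zero.

Standard errors are Huber-White sandwich estimates `H^-1 B H^-1` with B
the sum of per-person score outer products; `H^-1` alone is available as
the model-based alternative. Singularity of H is diagnosed on the
diagonally scaled matrix and reported with the parameter names aligned
with the null space. The standardized solution scales regressions by
model-implied predictor/outcome SDs and converts covariances to
correlations using the S-matrix variances of the two variables (for
within-wave residual covariances this is the innovation correlation);
growth-factor means and variances are reported raw and flagged. 95%
intervals for standardized quantities use the delta method with a
numerical Jacobian.

No scaled (Satorra-Bentler-type) test statistics are implemented: the
sandwich covariance is the only robustness device, and likelihood-ratio
tests are plain. In the package's own simulations (correct
specification, Gaussian data) the unscaled LRT is calibrated, which is
the regime the test suite certifies.

## Model comparison and fit

- Likelihood-ratio tests require fits to the same data (checked by a
  content hash) and a positive free-parameter difference.
- The univariate ladder fits levels 1–4 (autoregressive only; + random
  intercepts; + fixed slopes; + random slopes) and stops escalating when
  the LRT no longer prefers the larger model (p >= 0.05 by default).
  The level-1 model carries free per-wave observed means, so it is not
  parametrically nested in level 2 (whose means live on burst
  intercepts); that single step escalates by dominance — level 2 wins
  when it reaches a higher log-likelihood despite fewer parameters,
  which is decisive whenever random intercepts genuinely exist. Levels
  2 vs 3 and 3 vs 4 are ordinary nested LRTs (3 vs 4 tests a boundary
  variance and is therefore conservative).
- Fit indices: `T = 2(ll_sat - ll_model)` against the saturated model
  (closed form for complete data, EM for the multivariate normal under
  missingness); baseline is the independence model with free means and
  variances (closed form per column). CFI and TLI use their standard
  definitions; RMSEA uses n = number of persons (not n-1) with a 90%
  interval from inverting the noncentral chi-square; SRMR averages
  squared standardized residual moments with the mean structure
  included, denominator `p(p+1)/2 + p`. Adequacy thresholds: CFI/TLI
  >= 0.95, RMSEA/SRMR <= 0.05.

## Multiple groups

`split_groups` duplicates every free parameter per group (suffix
`@group`) unless its label family is named in the equality set. With no
equality constraints the joint ML factorizes and groups are fit
independently; with shared labels a joint optimization over the union
parameter vector is used. The default follows the group-specific
reporting convention (no invariance constraints), with equality
available as an option.

## Synthetic data

The generator mirrors the model as a forward structural recursion
(draw growth factors, then residuals wave by wave with cross-correlated
innovations) — deliberately independent of the RAM algebra, so that
agreement between generator sample moments and RAM-implied moments is a
genuine cross-module oracle. Defaults encode the study conditions the
package is tested under:

- 426 persons, 14 biweekly waves in two bursts of 7, one year apart.
- FI: intercept means 0.18 / 0.20, intercept variance 0.016, residual
  variance 0.003 (total SD ~0.14), autoregression 0.20.
- LS: intercept means 3.39 / 3.51, fixed slope means 0.02 / -0.01 per
  biweekly unit, intercept variance 0.45, residual variance 0.16,
  autoregression 0.10. The total LS SD (~0.78) is chosen so that the
  round-and-clip discretization to the 3–9 integer scale shifts wave
  means by less than 0.15 (floor clipping dominates this shift; with a
  total SD of 1.0 it would reach ~0.2).
- No cross-lagged effects; within-wave innovation correlation 0.15;
  intercept correlations 0.94 (FI across bursts), 0.92 (LS across
  bursts), 0.52–0.58 cross-construct.
- Monotone dropout with per-wave marginal retention shaped like the
  observed wave counts (426, 419, ..., 290, 202 out of 426), i.e. MCAR;
  an independent (non-monotone) mode exists, and retention of 1 gives
  complete data.
- Continuous output is the default (exactly Gaussian, used for recovery
  and moment oracles); `discretize_ls` and `clip_fi` produce the
  bounded/discrete realism variants used for robustness checks.

What the generator does *not* emulate: real item-level response
distributions, floor effects beyond clipping, sampling weights, or
informative dropout (an optional MAR mode conditioning on previous
frailty would be a small extension). Passing recovery tests on
continuous data therefore certifies the estimator, not the adequacy of
a Gaussian model for bounded, skewed real scales.

`simulate_items` inverts the frailty scoring for round-trip tests: given
target index values it emits binary deficit items whose rescored index
agrees within half an item, optionally with item-level missingness to
exercise the 80% validity rule.

## Problem sizes used in the checks

The calibration suite uses 50 replicates at n = 400 for parameter
recovery and interval coverage, 100 replicates per scenario for ladder
selection, 500 replicates for the 2-vs-3 type-I rate, 30 replicates for
fit-index adequacy, and 2x10^5 draws for the moment oracle. The moment
oracle compares 434 moments at once, so its band is set family-wise
(max |z| < 4.5) rather than per-entry; bias checks aggregate within a
parameter class (e.g. all 13 autoregressions of one construct) for the
same reason.

## Known limitations

- Gaussian likelihood for a bounded index and a discrete sum score; the
  generator quantifies the induced mean distortion (< 0.15 on the LS
  scale at the defaults) but the estimator does not model discreteness.
- No scaled chi-square variants or robust fit-index corrections.
- Construct names must be letter-only prefixes (`FI`, `LS`, covariate
  names likewise) because column/wave parsing splits on the trailing
  wave number.
- The level-1/level-2 dominance rule is a pragmatic device for a
  non-nested step; it does not produce a p-value.
- Multi-group standard errors are computed per group; no joint sandwich
  across equality-constrained groups.
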