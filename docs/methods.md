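# Methods

## Model

The core model decomposes log rates on an age × period Lexis grid into
additive age, period and cohort effects plus optional log-linear covariate
terms:

    y[a,t] ~ Poisson(n[a,t] * exp(eta[a,t]))
    eta[a,t] = mu + alpha_a + beta_t + gamma_c(a,t) + sum_k delta_k * x_k(t)

with `n[a,t]` person-years and `c(a,t) = M*(A-1-a) + t` the cohort index
(M = age-group width in period units, 5 by default: five-year age groups
over annual periods; cohorts sharing an index share one effect value).
A negative-binomial likelihood with estimated log-dispersion is available
behind the `overdispersion="on"` switch for data with extra-Poisson
variation; the default is Poisson, the standard choice for registry-style
event counts with a person-years offset.

Age, period and cohort effects are intrinsic Gaussian random walks,
order 2 by default (order 1 configurable per effect). Each random-walk
standard deviation carries a penalized-complexity (PC) prior — an
exponential distribution on sigma with rate `lambda = -ln(alpha)/U`, so
that `P(sigma > U) = alpha`. Defaults are `U = 1, alpha = 0.01` on the
log-rate scale: a smooth component is unlikely to wander more than one
log-unit, which is weakly informative for rates spanning a few orders of
magnitude across ages. The intercept and free covariate coefficients have
normal priors with standard deviation 10 (essentially flat at the scale of
log rates and elasticities).

### Identifiability

Individual APC effects are not identifiable: any linear-in-index function
can be shuffled between the three effects and the intercept without
changing `eta`. The package imposes an explicit constraint scheme —
default sum-to-zero on all three effects plus zero linear trend in the
cohort effect, so the common drift is carried by the period effect — and
treats `eta` (and everything derived from it: rates, ASRs, forecasts) as
the inferential output. A second scheme ("corner": first element of each
effect pinned to zero, first two cohort elements pinned) is provided, and
the test suite verifies that switching schemes moves the `eta` posterior
by less than Monte-Carlo noise. Effect curves are exposed for inspection
but should not be interpreted individually.

### Inference

Fitting follows the INLA logic at the scale this package targets
(single-stratum grids of a few hundred cells):

1. For fixed hyperparameters `theta` (log precisions of the three walks,
   plus log dispersion when overdispersed), the latent field is Gaussian
   a priori and the Poisson likelihood is log-concave, so the conditional
   posterior mode is found by a dense Newton iteration and the latent
   posterior is approximated by a Gaussian at that mode.
2. The Laplace approximation to the marginal posterior of `theta` is
   maximized by Nelder-Mead.
3. Hyperparameter uncertainty is integrated by sampling 25 `theta` points
   from the Gaussian (Laplace) approximation of their marginal posterior
   (numeric Hessian, central differences), re-solving the conditional mode
   at each point, and drawing the requested latent samples from the
   per-point Gaussians in rotation.

The default 1,000 joint posterior draws feed every downstream uncertainty
statement (Monte-Carlo quantiles with linear interpolation). All sampling
is driven by one explicit seed; fits are bit-reproducible.

Numerical guards: Newton uses step-halving with a small ridge fallback on
the Cholesky factor; hyperparameter proposals outside |log tau| of 40 are
rejected as degenerate; eigenvalues of the hyper-Hessian are floored at
0.16 so that a weakly identified precision is sampled with a standard
deviation of at most 2.5 on the log scale — wide enough to express real
uncertainty, bounded enough to keep every re-solved mode in a sane region.

The test suite checks the accuracy contract directly: on a 4×8 grid the
posterior mean of `eta` agrees with a long-run adaptive-Metropolis chain
(non-centered parameterization, 200k iterations) within 0.05 log-units
everywhere, and the observed agreement is about half that tolerance.

### Forecasting

Each posterior draw carries its own random-walk precisions. The period
effect — and the cohort effect, for cohorts that first enter the grid in
future periods — is continued per draw as a random walk of the fitted
order with that draw's innovation standard deviation; age effects are
held. Covariates extend by their scenario rule: hold-last-value (default,
conservative) or linear continuation of the observed OLS trend; series
stay centered at the observed-year mean so a constant covariate
contributes nothing. Age-specific rate draws `exp(eta)` are weighted into
ASRs and summarized by 2.5/50/97.5 percentiles. With RW2 components,
forecast variance grows roughly cubically in the horizon, which the
monotone-interval-width test confirms.

### Validation

`backtest` refits on a training window and scores the held-out years with
the posterior predictive of the *observable* rate: each posterior rate
draw is combined with Poisson noise at the held-out exposures. Scores
(MAE and RMSE of the predictive median, mean ensemble CRPS, 95%-interval
coverage) are computed on the log-rate scale by default, with a half-count
continuity correction `log((y + 1/2)/n)` applied jointly to predictions
and observations so sparse cells remain scoreable; the correction is
monotone in the count, so coverage is unaffected by it. Model criticism
reports DIC (posterior-mean plug-in), WAIC (variance form) and summed
log-CPO via the harmonic-mean estimator with an instability flag when the
weights' coefficient of variation exceeds 10 — the simple estimator is
kept deliberately, documented rather than refined.

## Synthetic data

The generator emulates the statistical structure the model assumes —
Poisson counts on a Lexis grid driven by additive log-rate surfaces over a
deterministic population pyramid — and emits the same comma-separated
dialect the readers consume, so every pipeline stage can be exercised
without any external download.

Default study conditions, chosen once as desk-scale analogues of a
1990-2021 national cancer-burden series: 18 five-year age groups (0-4
through 85 plus) × 32 annual periods; person-years
`n[a,t] = 1e6 * exp(-0.09 a) * 1.005^t` (oldest group about a fifth of
the youngest, ½% annual growth); quadratic log-rate age curve rising
about 0.45 per five-year group before flattening, intercept −8.1 placing
the all-age rate near 30 per 100,000 so total events are of order 3×10⁵;
period drift +1%/year; sinusoidal cohort wave of amplitude 0.15 with a
60-cohort wavelength; optional declining exposure covariate
(`x(t) = 0.40 − 0.005 t`) with elasticity 1.2. Scenarios nest:
`age_only` → `drift` → `full_apc` → `covariate`. Constructed curves are
returned in constrained form with the removed constants and linear trends
folded back into the intercept, age curve and drift, so the emitted
surface equals the designed one exactly (a property the tests assert).

For calibration experiments, `generate_model_truth` instead draws the
period and cohort curves as genuine RW2 sample paths (innovation scales
0.015 and 0.003, set so realized curve amplitudes match the deterministic
scenarios — an order-2 walk's realized scale grows like `sd * m^{3/2}`).
Data for coverage claims must come from the stochastic family the model
assumes; smooth deterministic curves are "easier" than RW2 paths and make
predictive intervals look conservative.

What the generator does **not** emulate: estimation-pipeline artifacts of
real burden databases (under-reporting correction, covariate imputation,
pandemic disruption adjustment), reporting-induced correlation between
strata, or real-location heterogeneity. Passing tests therefore
demonstrate the statistical machinery is correct and calibrated under its
own assumptions — not that real registry data satisfy those assumptions.

## Design choices made where the design was open

- **EAPC**: log-linear OLS of ln(ASR) on calendar year,
  `EAPC = 100(e^beta - 1)`, CI transformed from the slope's normal
  interval — the standard definition consistent with "EAPC (95% CI)"
  reporting.
- **Standard population**: no single standard is canonical; the WHO
  2000-2025 world standard (20 five-year groups) ships as the builtin,
  with collapse-to-coarser-groups support, and any two-column CSV can be
  substituted. Comparative claims should state the standard used.
- **Covariate elasticities**: estimated jointly from the data under the
  weak normal prior by default, with an option to fix them to externally
  supplied values. A covariate that is smooth in time is partially
  confounded with the period random walk; its posterior is honest about
  that (wide), which the coverage-over-replicates test confirms.
- **Risk attribution**: PAFs are applied at the finest common stratum and
  never summed across nested risk categories (behavioral ⊃ smoking, etc.),
  since PAFs are not additive.
- **Sex pooling**: strata are fit independently; the "both" stratum is a
  fit of pooled counts, not an average of sex-specific forecasts
  (asserted by a construction test).
- **SDI quintiles**: rank-based with configurable cutpoints, equal mass by
  default, ties broken by location label for determinism.

## Problem sizes used by the test and acceptance runs

Unit tests run on 4×8 to 6×16 grids; the statistical acceptance checks use
the full 18×32 study grid with 50 replicate datasets for the coverage and
back-test calibration experiments, and a 200k-iteration MCMC oracle on the
4×8 grid. The complete suite runs in a few minutes on one core; a single
18×32 fit with 1,000 posterior draws takes well under a second.

## Known limitations

- The Gaussian approximation at the conditional mode ignores the skewness
  of the Poisson posterior; at cell counts below ~10 the posterior mean of
  `eta` can be biased by a few hundredths and credible intervals in those
  cells run below nominal coverage (the aggregate stays within the tested
  [0.90, 0.98] band). Simplified-Laplace mean corrections are out of scope.
- Harmonic-mean CPO is unstable for influential cells; the instability
  flag is the only mitigation.
- Forecasts inherit the usual APC caveat: the period/cohort split of the
  drift is a modelling convention, and long-horizon bands assume the
  random-walk mechanism persists.
- No spatial pooling or cross-stratum hierarchy: each stratum is fit
  independently.
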