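# Methods

## The problem

Longitudinal studies in ecology and evolution routinely regress a response
`Y_t` (a vital rate, reproductive output, dominance) on a contemporaneous
covariate `X_t` (population size, group size, somatic growth).  In many of
these systems the covariate is *endogenous*: it depends on the response of
the previous time step through a cross-lag (population size on past
productivity and survival, group size on past recruitment, growth on past
reproductive costs).  Static regressions that treat `X` as exogenous are
then biased in short series, in the direction *opposite* to the sign of
the cross-lag, and collecting more subjects does not remove the bias when
inference targets within-subject patterns.  This package simulates the
canonical cross-lagged processes, fits the competing estimators, and
quantifies the bias and power surfaces by Monte Carlo.

## Data-generating processes (`crosslag.procsim`)

Four Gaussian processes are implemented, all with white innovations and,
for the multi-subject kinds, bivariate-normal random intercepts
`(mu_s, nu_s) ~ MVN(0, Omega)` drawn once per subject:

| kind | equations | cross-lag | among-subject terms |
|---|---|---|---|
| `tradeoff_single` | `Y_t = a + bX_t + eps`, `X_t = c + dY_{t-1} + kappa` | simple, `d<0` typical | none |
| `tradeoff_multi`  | as above with `mu_s` on Y, `nu_s` on X | simple | `Omega` full |
| `density_single`  | `X_t = c + dY_{t-1} + f Z_{t-1} X_{t-1} + kappa`, `Z_t = g + lambda` | interacting cross- and auto-lag, `d>0` | none (replicate populations permitted) |
| `grouplive_multi` | as density, with `mu_s` on Y and `nu_s` on Z | cross- plus auto-lag | `Omega` full |

Initialization: every subject starts at the deterministic fixed point of
its recursion and the first `burn_in` steps (default 100) are discarded,
so retained series are effectively stationary.  Stationarity guards are
enforced at construction (`|bd| < 1`, linearized persistence
`|bd + fg| < 1`) and any trajectory exceeding `1e6` raises an explosion
error rather than silently overflowing.

Parameter defaults are this package's own (per-kind `default_spec`):
trade-off `a=0, b=0.5, c=0, d=-0.5`, unit noise SDs, intercept SDs 0.75
with correlation +0.5; density `a=2, b=-0.3, d=0.5, f=1, g=0.7`, noise SDs
(0.5, 0.5, 0.1); group living `a=2, b=0.25, c=0.5, d=0.4, f=1, g=0.6`,
intercept SDs (0.4, 0.06) with correlation +0.5.  They were chosen once to
satisfy the stationarity constraints and to make the short-series bias
clearly visible at `T = 10`; they are not tied to any external dataset.

Measurement error (`add_measurement_error`) appends contaminated columns
`X_obs = X + theta`, `Y_obs = Y + eta` with independent Gaussian errors
whose variance is `frac/(1-frac)` times the *empirical* variance of the
true values, so that the error accounts for the stated fraction of total
observed variance and the implied reliability (correlation between two
independent measurements of the same truth) is `1 - frac`.

## Estimators (`crosslag.estimators`)

All five estimators return the contemporaneous effect `b_hat` with a Wald
SE, normal-based 95% interval, two-sided p-value, log-likelihood and a
standardized effect `b * sd(X)/sd(Y)` (a variance-ratio variant is
available; the SD convention is this package's choice where either reading
is defensible).

* **STAT_OVERALL** — `Y ~ 1 + X + (1|subject)`, Gaussian ML.  Implemented
  by a profiled solver: for a random-intercept model the likelihood
  reduces to a one-dimensional search over the variance ratio
  `tau^2/sigma^2` with closed-form GLS at each value (Woodbury identity
  per group).  This is an exact ML fit — it agrees with statsmodels
  MixedLM to numerical tolerance in the test suite — but is roughly an
  order of magnitude faster, which matters at tens of thousands of
  Monte-Carlo refits.
* **STAT_WITHIN** — the same model on within-subject-centred X.
* **DYN_LDVM** — adds within-subject-centred `Y_{t-1}`; first rows (and
  rows following a time gap) are dropped.
* **DYN_SEM** — the dynamical structural-equation model.  Conditional on
  observed lagged covariates, the Y-, X- and (where applicable) Z-equations
  form a stacked linear mixed model with response-specific residual
  variances and marginal covariance `L Omega L' + R` per subject; the
  random intercepts are integrated out analytically.  Fixed effects are
  profiled by GLS, the variance parameters (log residual SDs, Cholesky of
  `Omega`) are maximized by L-BFGS with an analytic envelope-theorem
  gradient, and subjects sharing a series length share one Cholesky
  factorization per likelihood evaluation.  Convergence is declared on
  relative likelihood change below 1e-12 (optimizer default tolerances
  otherwise); a Nelder-Mead polish runs only if L-BFGS reports failure.
* **DYN_SEM+** — the errors-in-variables extension with *known* error
  variances.  Conditional on the exactly observed `Z`, the latent system
  is linear Gaussian even for the product auto-lag (the coefficient
  `f*Z_{t-1}` is data), so the state `(X'_t, Y'_t, mu_s, nu_s)` follows a
  time-varying linear state-space model and a Kalman filter returns the
  exact marginal likelihood with latent series and intercepts integrated
  out.  The filter is a compiled scalar loop (numba) with a vectorized
  numpy fallback; optimization is L-BFGS from two warm starts (the naive
  fit on observed values, and a deattenuation-corrected version of it),
  keeping the better optimum — with substantial predictor error the naive
  optimum can sit in the wrong basin.  With both error variances exactly
  zero the measurement layer is the identity and the fit delegates to
  DYN_SEM.

### Initial conditions

Under stationarity each subject's first observation is correlated with its
random intercepts (a subject with high `nu` enters the study with high X).
Conditioning on `X_1` while treating the intercepts as independent of it
is therefore mildly misspecified, and measurably biases `b_hat` in the
group-living structure.  DYN_SEM consequently includes an
initial-condition submodel whenever random intercepts are present: `X_1`
gets a free mean, free loadings on `(mu, nu)` and a free residual SD (the
standard initial-conditions device for dynamic panel likelihoods).  For a
single subject the random terms vanish, pure conditioning applies, and the
`b` estimate coincides *exactly* with STAT_OVERALL's — single series
contain no information that separates the within- from the among-subject
channel.  DYN_SEM+ does the analogous thing: the trade-off structure uses
the exact stationary joint of `(X'_1, Y'_1, mu, nu)` (available in closed
form for the time-invariant transition), while the Z-carrying structures —
whose product process has no Gaussian stationary law — use the same free
initial-condition parameterization for the first latent X.

### Deliberate misspecification switches

`fit_dyn_sem` exposes `include_crosslag=False` (drops the `d` path) and
`correlated_intercepts=False` (keeps both intercepts but fixes their
covariance to zero).  The intercept *correlation* is the only parameter
shared between the equations; severing it reverts `b_hat` to the static
mixed-model estimate, which is how the necessity of both ingredients is
demonstrated in the experiment suite.

## Monte-Carlo engine (`crosslag.experiments`)

`run_grid`, `run_sweep` and `power_analysis` share one paired-replicate
core: replicate `r` of a cell simulates with `seed + r` and fits *every*
requested model to the identical panel, so model contrasts are free of
simulation noise.  Summaries per cell and model: mean estimate, relative
bias in percent (absolute bias, flagged, where the true effect is zero),
Monte-Carlo SE from the replicate spread, rejection rate of the Wald test
at `alpha` (power / type-I error), and the convergence rate;
non-converged fits are excluded with counts reported.  Reruns with the
same seed reproduce summaries bit-for-bit.  Default `n_reps` is 1,000,
configurable upward; the shipped reproduction script uses 200–600
replicates per cell (25–60 for the errors-in-variables fits, whose refits
are ~100x more expensive), sizes chosen to keep full reproduction on a
laptop-class single core comfortable while leaving Monte-Carlo SEs a
small fraction of the effects being measured.

## Diagnostics (`crosslag.diagnostics`)

`crosslag_correlation` correlates `X_t` with `Y_{t-1}` strictly within
subjects (both centred on subject means over the contributing pairs, so
the statistic is invariant to subject-level shifts), with a Fisher-z CI
using the number of pairs as effective sample size — a pragmatic choice;
autocorrelated pairs make it mildly anti-conservative.  The output is
labelled as a *necessary, not sufficient* indication of a causal
cross-lag.  `variance_growth` profiles `Var(X_t)` across replicates from a
degenerate start; its rise-and-plateau shape is the mechanism by which
static-model bias fades in long series.

## Group-living case study (`crosslag.casestudy`)

The discrete-response analogue of the group-living process for
cooperatively breeding birds: productivity (offspring surviving to the
next season) is Poisson with log-link in group size with a group intercept
`m_g`; group size is Poisson with *natural-scale* mean
`c + d*productivity_{t-1} + survivors_{t-1}` (the identity-scale
composition matches the mechanistic recruitment story, and `d` reads as a
per-offspring recruitment probability; a log-link variant would be the
obvious alternative and was not adopted because it destroys that reading);
survival is Binomial with logit intercept plus a second group effect
`n_g`, and `(m_g, n_g)` are correlated (LKJ(2) prior on the correlation,
half-Normal(1) on the SDs, Normal(0, 1.5) on coefficients — weakly
informative on these scales).  Group sizes never fall below the breeder
pair, so observed sizes of 2 are treated as left-censored Poisson
observations; ignoring the floor attenuates `d` noticeably on synthetic
data.  Rows whose lagged predictors cross a year gap enter only the
submodels whose predictors exist.

Sampling is adaptive Metropolis-within-Gibbs: group-level effects are
conditionally independent given the hyperparameters and are updated with
vectorized per-group proposals; global blocks use adaptive random walks;
two non-local moves fight the ridges typical of hierarchical GLMMs — a
translation move shifting an intercept against the latent means
(likelihood-invariant) and a shear move along the `b`-vs-group-intercept
ridge.  Four chains by default, 1,000 warmup + 1,000 draws; split-chain
R-hat and bulk ESS (arviz) are reported for every parameter and R-hat
above 1.01 is surfaced as a warning on the result rather than an
exception.  Effects are reported as `100*(exp(b)-1)` percent change in
expected productivity per additional group member.

The wren-like generator plants a known effect (`b = log(1.12)`, i.e. +12%)
in a philopatry-driven recruitment loop: next season's group is the
binomial survivors plus binomially recruited previous offspring plus rare
Poisson immigration, floored at the breeder pair and capped at a territory
capacity of 10, with correlated group heterogeneity in productivity and
survival.  Defaults (productivity intercept `log 0.75` at the reference
size of 5, survival ~0.85, recruitment probability 1.0, immigration 0.05,
group SDs 0.4/0.6 with correlation 0.6) represent the strong-philopatry
regime at the scale of a ~100-group, 9-year field study.  In this regime
the within-group static estimate is pulled far below the truth; in very
short panels (5–6 seasons) its posterior mean typically goes *negative*
while the joint dynamical model stays at ~+12% — the qualitative
static-vs-dynamic sign flip.  The generator emulates count noise,
philopatry and heterogeneity but not dispersal structure, detection error,
environmental year effects or overdispersion, so passing tests say the
pipeline recovers effects under its own assumptions, not that any field
dataset satisfies them.

## Known limitations

* The Gaussian simulator covers the four canonical structures only;
  discrete-response generation lives solely in the case-study module.
* DYN_SEM+ assumes balanced panels and error variances known from external
  information (e.g. repeat measurements); it does not estimate them.
* For the Z-carrying structures the first-latent-state model is a Gaussian
  approximation with free loadings; its adequacy is checked empirically
  (bias within a few percent at `S=100, T=10`) rather than guaranteed.
* The case-study MCMC is a random-walk scheme: effective sample sizes per
  draw are modest compared to gradient-based samplers, and the group-SD
  and correlation parameters mix slowest; raise `draws` if their R-hat
  warnings appear.
* Single-series panels identify `b` only through the static channel; no
  estimator here (or, to our knowledge, elsewhere) removes short-series
  cross-lag bias with one subject — the package reports it rather than
  fixing it.
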