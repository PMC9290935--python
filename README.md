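# crosslag

Simulation and unbiased estimation for **cross-lagged ecological time
series**.

Longitudinal studies in ecology and evolution often regress a response
`Y_t` on a contemporaneous covariate `X_t` — vital rates on population
size, group productivity on group size, reproduction on somatic growth.
In many of these systems the covariate is *endogenous*: a **cross-lag**
makes `X_t` depend on the previous response `Y_{t-1}` (population size is
built from past reproduction and survival; group size from past recruits;
growth from past reproductive costs).  Static regressions that treat `X`
as exogenous are biased in short time series, in the direction opposite
to the sign of the cross-lag — toward "detecting" density dependence and
against detecting trade-offs or benefits of group living — and adding
more subjects does not help when inference targets within-subject
patterns.  Measurement error adds its own, sometimes opposing, bias.

`crosslag` is a toolkit for studying and avoiding this problem:

* **`crosslag.procsim`** — generators for the canonical cross-lagged
  processes (trade-off, density dependence, group living), e.g. the
  multi-subject trade-off

  ```
  Y[s,t] = a + b·X[s,t] + mu_s + eps[s,t]
  X[s,t] = c + d·Y[s,t-1] + nu_s + kappa[s,t],   (mu_s, nu_s) ~ MVN(0, Omega)
  ```

  plus a measurement-error overlay sized as a fraction of total variance.
* **`crosslag.estimators`** — five comparable estimators of the
  contemporaneous effect `b`: static mixed models on raw and
  within-subject-centred covariates (`STAT_OVERALL`, `STAT_WITHIN`), a
  lagged-dependent-variable model (`DYN_LDVM`), a dynamical
  structural-equation model with correlated random intercepts fitted by
  exact marginal maximum likelihood (`DYN_SEM`), and its
  errors-in-variables extension with known error variances, evaluated by
  Kalman filtering (`DYN_SEM_PLUS`).
* **`crosslag.experiments`** — a paired-replicate Monte-Carlo engine for
  bias and power surfaces over subjects × series-length grids and
  parameter sweeps; usable as a study-design power tool.
* **`crosslag.diagnostics`** — empirical cross-lag checks (within-subject
  correlation of `X_t` with `Y_{t-1}`; variance-growth profiles).
* **`crosslag.casestudy`** — a Bayesian Poisson/binomial pipeline for
  group-living count panels (static within-group versus joint dynamical
  model), with a wren-like synthetic generator for validation.

A command-line interface (`crosslag simulate | fit | experiment | sweep |
power | diagnose | casestudy`) wraps the library; every output embeds the
configuration hash and seed.

## Worked example

Simulate a life-history trade-off panel (100 individuals, 10 seasons,
true effect `b = 0.5`, cross-lag `d = -0.5`, positively correlated
individual quality) and compare the estimators:

```python
import crosslag as cl

spec = cl.default_spec("tradeoff_multi", seed=42)   # S=100, T=10
panel = cl.simulate(spec)

for fit in (cl.fit_stat_overall(panel),
            cl.fit_stat_within(panel),
            cl.fit_dyn_ldvm(panel),
            cl.fit_dyn_sem(panel, "tradeoff")):
    print(f"{fit.model:13s} b_hat = {fit.b_hat:.3f}  (SE {fit.se_b:.3f})")
```

```
STAT_OVERALL  b_hat = 0.532  (SE 0.029)
STAT_WITHIN   b_hat = 0.537  (SE 0.030)
DYN_LDVM      b_hat = 0.527  (SE 0.036)
DYN_SEM       b_hat = 0.505  (SE 0.029)
```

Both static fits overshoot the true `b = 0.5` (the negative cross-lag
pushes within-subject estimates up, and the positive among-individual
covariance pushes the cross-sectional one up); the dynamical SEM, which
models the cross-lag and the correlated intercepts jointly, lands on it.
The diagnostic confirms the cross-lag signature that warrants the
dynamical model:

```python
from crosslag.diagnostics import crosslag_correlation
rec = crosslag_correlation(panel)
print(rec.r, rec.n_pairs)    # -0.551, 900  (negative, as a cost of
                             # reproduction implies; necessary, not
                             # sufficient, evidence of a causal cross-lag)
```

Averaged over many replicates the single-panel impression above becomes
systematic: with these defaults the static models are biased by about
+5% to +6% while DYN_SEM is unbiased to Monte-Carlo precision — see the
reproduction script below.  The same machinery quantifies power, e.g.
that at 1,000 subjects and 5 time steps a static fit rejects `b = 0` in
every replicate while being ~30% biased.

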