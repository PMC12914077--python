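# hrrmap

Bayesian spatiotemporal multilevel disease mapping with **hierarchical
related regression** (HRR).

## The problem

Thirty-day mortality after starting systemic anticancer therapy (SACT) is a
widely used quality indicator for lung-cancer care: patients who die within
a month of starting treatment were unlikely to benefit from it.  Early
mortality varies both with individual characteristics (age, clinical stage,
performance status, multidisciplinary review, supportive-care screening,
comorbidity) and across the small areas where patients live.  Estimating
how much of the geographic variation is structured — spatially correlated
risk shared by neighboring areas — versus idiosyncratic, while adjusting
for individual case mix, requires a model that joins both levels without
incurring ecological bias.

`hrrmap` implements that analysis as a reusable, fully tested pipeline for
epidemiologists and biostatisticians working with registry extracts: one
row per patient with an area id, a time period, categorical covariates and
a binary outcome, plus an area adjacency structure.

## The model

Individual outcomes are multilevel logistic,

```
y_ijt ~ Bernoulli(p_ijt)
logit(p_ijt) = mu + beta' x_ijt + gamma' z_j + u_j + v_j + d1 c(t) + d2 c(t)^2
```

with `u` a Besag intrinsic CAR (ICAR) field over the Queen-1 contiguity
graph (`u_i | u_-i ~ N(neighbor mean, tau_u^2 / n_i)`, sum-to-zero per
component), `v` i.i.d. normal heterogeneity, and centered linear +
quadratic period terms.  Aggregate area-period death counts follow

```
y_jt ~ Binomial(N_jt, p_jt),   p_jt = sum_k f_jtk p_jtk
```

where `f_jtk` is the empirical joint within-area distribution of the
individual covariates over strata `k` — the HRR marginalization that
protects the aggregate level from ecological bias.  The full likelihood is
the product of the two levels.  Coefficients carry Normal(0, precision
0.725) priors (a 95% prior odds-ratio interval of 0.1–10), the intercept is
flat, and the precisions have Gamma(0.5, 0.0005) hyperpriors.  Posterior
sampling is a native adaptive Metropolis-within-Gibbs engine (numba-
compiled); convergence is monitored with Brooks–Gelman–Rubin statistics and
batch-means Monte-Carlo errors, model choice with DIC and a five-point
forward-selection rule.

Because the motivating registry is available only on request, the package
ships a first-class synthetic-registry generator that mirrors the fitted
model exactly (published covariate marginals, published adjusted odds
ratios as true effects, ICAR spatial field, calibrated intercept), making
parameter recovery a well-posed end-to-end test.

## Worked example

```python
from hrrmap import (SimulationConfig, simulate_registry, build_cells,
                    SamplerConfig, run_mcmc, aor_table,
                    spatial_variance_fraction)

cfg = SimulationConfig(n_areas=20, lattice_dims=(4, 5),
                       n_patients=4000, seed=1)
reg = simulate_registry(cfg)                     # synthetic study
cells = build_cells(reg.records, reg.z, reg.adjacency)
fit = run_mcmc(cells, reg.adjacency,
               SamplerConfig(n_iterations=10_000, burn_in=5_000,
                             n_chains=2, seed=1))
print(aor_table(fit).loc[["beta:stage_IV", "beta:scs_yes"]].round(2))
print(f"structured share: {spatial_variance_fraction(fit):.1f}%")
```

prints

```
                aor  lower  upper  significant
parameter
beta:stage_IV  3.24   1.19   7.64         True
beta:scs_yes   0.50   0.35   0.70         True
structured share: 68.8%
```

i.e. the fit recovers the generator's stage-IV odds ratio (true value 3.19)
and supportive-care-screening odds ratio (true 0.53) with 95% credible
intervals covering the truth, and attributes about two thirds of the
spatial variation in this 20-area replicate to the structured (ICAR)
component.

A command-line interface mirrors the pipeline:

```bash
hrrmap simulate --out data/
hrrmap fit --data data/ --iterations 20000 --burn-in 10000 --out draws.csv
hrrmap diagnose --data data/ --out report.json
hrrmap map --data data/ --out maps/
```

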