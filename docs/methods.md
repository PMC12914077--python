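# Methods

## Model

The package estimates small-area, multi-period variation in a rare binary
outcome (the motivating application is death within 30 days of starting
systemic anticancer therapy) using a hierarchical related regression (HRR):
two likelihood levels share one set of parameters.

**Individual level.**  For patient *i* in area *j* and period *t*,

    y_ijt ~ Bernoulli(p_ijt)
    logit(p_ijt) = mu + beta' x_ijt + gamma' z_j + u_j + v_j
                   + delta1 c(t) + delta2 c(t)^2

where `x` are individual categorical covariates (dummy-coded against
reference levels: age ≤ 60, no multidisciplinary-meeting presentation, no
supportive-care screening, stage I, no comorbidity, good ECOG status), `z`
area-level covariates (socioeconomic-quartile dummies against the most
disadvantaged quartile), `u` the structured and `v` the unstructured
spatial effects, and `c(t) = t − (T+1)/2` the centered period index
(`t − 2` for three periods), which removes the collinearity between the
linear and quadratic terms.

**Aggregate level.**  Area-period death counts are

    y_jt ~ Binomial(N_jt, p_jt),    p_jt = sum_k f_jtk p_jtk

with `f_jtk` the joint within-area distribution of the individual
covariates over the K = 2·2·2·4·2·3 = 192 strata, estimated empirically per
(area, period); empty cells contribute no likelihood term.  Marginalizing
the individual model over `f` is what removes ecological bias from the
aggregate level.  A Poisson alternative (mean `N_jt p_jt`) is selectable;
for risks below 5% the two agree to within a few percent, and an
overdispersion check (Pearson X²/df with a parametric-bootstrap p-value)
reports whether the Poisson mean-variance assumption is tenable.  The full
likelihood is the product of the two levels.  With a complete individual
registry the aggregate counts are a deterministic function of the same
records, so the product double-counts information that both levels carry
(the spatial and temporal terms in particular); this is the construction as
published and is kept as the default, with `use_aggregate=False` available
to fit the individual level alone.

**Priors.**  Regression coefficients (beta, gamma, delta): Normal with
mean 0 and precision 0.725, the precision implied by a 95% prior
probability that an odds ratio lies in (0.1, 10) — precision
= (z_0.975 / ln 10)² ≈ 0.7245.  Intercept: improper flat.  Structured
effects: Besag ICAR, `u_i | u_−i ~ N(neighbor mean, tau_u²/n_i)` on the
Queen-1 contiguity graph (binary weights, shared edge or vertex), with a
sum-to-zero constraint per connected component and `u ≡ 0` for isolated
areas.  Unstructured effects: i.i.d. N(0, tau_v²).  Precisions 1/tau_u²
and 1/tau_v²: Gamma(0.5, 0.0005), the common disease-mapping default; both
hyperparameters are configurable for sensitivity analysis.

## Sampler

A native Metropolis-within-Gibbs engine (numba-compiled kernel) operating
on records collapsed to (area, period, stratum) cells — patients in a cell
share a linear predictor, so the Bernoulli product reduces exactly to
per-cell binomial kernels and every update touches only the affected cells.
Per sweep:

1. scalar random-walk Metropolis for each fixed effect;
2. five joint random-walk moves over the whole fixed-effect block, with
   proposal covariance 2.38²/F times the running chain covariance
   (Haario-style adaptive Metropolis).  These moves exist because the
   intercept and covariate coefficients are strongly correlated a
   posteriori — the stage-I reference category is nearly empty at realistic
   compositions — and single-site moves traverse that ridge slowly;
2a. likelihood-invariant translation moves per area-level coefficient, run
   three times per sweep through each of two routes: shifting gamma_q by d
   while subtracting d·(z_q − mean z_q) from u and d·mean z_q from the
   intercept (active on connected maps), or while subtracting d·z_q from
   the unstructured field v.  Both leave every linear predictor unchanged,
   so acceptance depends only on the priors; they decorrelate the area
   coefficients from the spatial fields, which otherwise form the slowest
   posterior direction;
3. single-site random-walk Metropolis for each `u_j` (prior part from the
   ICAR full conditional) and each `v_j`, with proposals scaled by an
   approximate full-conditional standard deviation
   `1/sqrt(prior precision + likelihood information)` so the adapted scale
   stays valid as the precision parameters move;
4. sum-to-zero re-centering of `u` (per component); for a connected map the
   mean shift is added to the flat-prior intercept, which leaves the
   posterior density unchanged;
5. conjugate Gibbs draws for both precisions:
   `1/tau_u² ~ Gamma(a + rank/2, b + SS_u/2)` with `SS_u` the sum of squared
   neighbor differences and rank = areas − components, and the analogous
   draw for `1/tau_v²`.

Scalar proposal scales adapt toward 0.44 acceptance and the block scale
toward 0.234 (Robbins–Monro on the log scale, step floored at 0.05 so the
adaptation can track slowly drifting hyperparameters), during burn-in only;
everything is frozen afterwards, so the retained draws come from a fixed
transition kernel.  Chain state is refreshed from scratch every 1,000
sweeps to cancel incremental round-off; deviance (−2 log joint likelihood,
in the fitted family) is stored per retained draw for DIC.  Chain 1 starts
at zero effects and unit precisions; later chains start over-dispersed at
±1 prior standard deviation on the fixed effects so between-chain
diagnostics are meaningful.  Runs are bit-reproducible given the seed and
chain count.

The full published protocol — 100,000 iterations, 50,000 burn-in, 2 chains —
is the package default.  Tests and the acceptance script use desk-scale
runs of the same sampler (2 × 10,000 sweeps on 20-area, 4,000-patient
registries; 2 × 6,000 on smaller fixtures), sizes chosen so the entire
suite runs comfortably on one CPU while leaving the convergence gates
meaningful.

## Diagnostics and model selection

* **BGR** — the Gelman–Rubin potential scale reduction
  `sqrt(((n−1)/n · W + B/n)/W)`; identical chains give the analytic floor
  `sqrt((n−1)/n)`.  Automated flag at 1.1 (the published analysis relied on
  plots; a numeric gate is needed for CI).
* **MC error** — batch means with 50 batches; pass when MC error < 5% of
  the posterior standard deviation (the BUGS convention; the denominator is
  the posterior sd).  Multi-chain MC error is the root-mean-square of
  per-chain errors over `sqrt(n_chains)`.
* **DIC** — `Dbar + pD`, `pD = Dbar − D(posterior means)`, evaluated with
  the same likelihood family the model was fitted with.  Forward selection
  starts from the lowest-DIC single-variable model and retains an addition
  only when DIC drops by at least five points (a drop of exactly five
  counts).

## Synthetic-data generator

The generator mirrors the fitted model exactly — the published analysis
provides no generative recipe, and simulating from the assumed model makes
parameter recovery a well-posed test.  Defaults reproduce the published
study conditions:

* 79 areas (a near-square unit lattice truncated to the area count stands
  in for the real administrative map), 3 periods, 6,704 patients allocated
  uniformly to areas and periods;
* covariate marginals from the published cohort composition (76.88% aged
  over 60, 66.33% presented at a multidisciplinary meeting, 44.42%
  screened for supportive care, stages I–IV renormalized over stated stages
  to 3.41/8.07/24.00/64.52%, 52.51% with comorbidity, ECOG
  62.26/9.84/27.89% good/poor/not-stated), drawn independently per patient;
* true log-odds ratios are the logs of the published adjusted ORs
  (age 1.06, MDM 0.66, SCS 0.53, stage II/III/IV 1.15/1.28/3.19,
  comorbidity 1.12, poor ECOG 3.09).  The not-stated ECOG level has no
  published adjusted OR; its default is the log of the crude OR vs. good
  status (≈ 2.22).  Area socioeconomic effects default to the logs of the
  crude quartile ORs (−0.15, −0.25, −0.48 vs. the most disadvantaged
  quartile); remoteness is carried in the area table as a descriptive
  column but given no effect, since the published adjusted model retains no
  remoteness term;
* temporal coefficients default to delta1 = −0.10, delta2 = 0.05 — a modest
  decline that flattens in the last period, a realistic shape for a
  treatment-quality indicator; the published analysis reports no temporal
  effect sizes;
* the intercept is calibrated by 1-d root finding so the expected overall
  outcome rate equals the published 4.25% given the marginals and effects
  (the expectation ignores the spatial fields' Jensen gap, which is far
  below sampling error at these sizes);
* spatial scales default to tau_u² = 0.4 (ICAR conditional-variance scale)
  and tau_v² = 0.015, which on the default 79-area map put the structured
  share of marginal spatial variance near the published ≈ 7/8.  The ICAR
  field is drawn exactly via the Laplacian eigendecomposition (variance
  tau_u²/λ along each non-null eigenvector), centered per component.

What the generator does **not** emulate: informative patient-to-area
allocation (case mix is independent of area beyond the area-level effects),
within-patient covariate correlation (covariates are drawn from independent
marginals, so the synthetic `f_jtk` has product structure plus sampling
noise), repeated treatment episodes, and real administrative geography.
Passing recovery tests therefore demonstrate the estimator's correctness
under the model's own assumptions, not robustness to their violation.

## Reporting

* Crude rates as percentages to 2 dp with Wilson score intervals (the score
  interval reproduces the published 95% CI for the overall rate exactly at
  the printed precision).
* Odds-ratio tables exponentiate posterior draws and summarize with the
  mean and equal-tailed 95% credible interval; a coefficient is flagged
  significant when the interval excludes 1.
* **Standardized relative risk (SRR)**: per posterior draw, each
  (area, period) risk is recomputed over the pooled covariate distribution
  (at-risk-weighted strata frequencies of the whole study) and divided by
  the at-risk-weighted average of those standardized risks; summaries are
  the posterior mean, 95% interval and exceedance probability P(SRR > 1).
  The source analysis does not define its SRR; this covariate-standardized
  ratio is the declared choice, isolated behind one function.
* **Structured variation share**: per draw, var(u)/(var(u)+var(v)) across
  areas; the posterior mean is reported as a percentage.  Whether the
  published share uses this partition or another decomposition is not
  stated; this metric is declared, not claimed to match.
* Choropleth export writes one GeoJSON per period with SRR mean, interval,
  and exceedance as feature properties.

## Numerical choices and edge cases

* Cell risks are clipped to [1e-12, 1 − 1e-12] inside the sampler; a
  non-finite retained deviance aborts the run with the offending state.
* Empty (area, period) cells: `N_jt = 0`, no aggregate term, SRR reported
  as missing and flagged.
* Disconnected maps get one sum-to-zero constraint per component; isolated
  areas have `u_j ≡ 0` and are skipped by the structured-effect update.
* The ICAR rank used in the precision Gibbs step is areas minus components.
* `estimate_f` is per (area, period); with sparse cells the empirical `f`
  is noisy but always a valid probability vector over occupied cells.
* Ties at the DIC five-point boundary count as retention.

## Known limitations

* The joint likelihood double-counts a fully observed registry (see above);
  credible intervals for parameters informed at both levels (intercept,
  temporal terms, area effects) are accordingly somewhat narrower than
  their pure individual-level counterparts.
* Proper-CAR correlation parameters, BYM2 reparameterization, higher-order
  contiguity, and survey-weighted HRR variants (individual and aggregate
  data from different sources) are out of scope.
* The period-level quadratic trend is a fixed effect; a period random
  intercept is not fitted by default.
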