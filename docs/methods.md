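# Methods

## Model and estimation

All three families regress a non-negative council count on covariates through
the log link, `ln mu_i = x_i' beta`. The log-likelihoods are evaluated in log
space with log-gamma terms; the generalized Poisson (GP) uses the
mean/dispersion-factor form with parameters `(mu, theta)`, where
`theta = 1/(1 - delta)` maps to the classical `(alpha, delta)` form via
`mu = alpha/(1 - delta)`. GP feasibility, `theta >= max(1/2, 1 - mu/4)`, is
enforced as stated in the literature for the mean parametrization; we do not
extrapolate other bounds. Points violating it (for any observation) receive a
penalty objective value rather than being projected back, so the reported
optimum is a genuine interior maximizer.

Estimation is direct maximum likelihood over `(beta, log dispersion)`:

- **Dispersion link.** NB2's `alpha` and GP's `theta` are estimated as
  `log(alpha)` / `log(theta)` — one free dispersion-equation intercept each.
  This gives positivity without constrained optimization. The z/p row
  reported for the dispersion parameter refers to the log-scale parameter.
- **Optimization.** BFGS with *analytic* gradients (the score equations of
  all three families are closed-form; using them makes the convergence
  criterion meaningful and replicate studies fast), started from the Poisson
  solution with the dispersion at a Pearson-ratio moment estimate. A few
  Newton polish steps off the numerical Hessian follow if BFGS stalls short
  of the tolerance.
- **Convergence.** Declared when the max-norm of the per-observation score
  (mean negative log-likelihood gradient) falls below 1e-6 — equivalently a
  total-score norm below 1e-6·n, the same scale as the Poisson score
  identity `sum(y - mu_hat) ≈ 0` the tests assert. The flag is honest:
  non-convergent fits are returned flagged, and the pipeline degrades
  gracefully (a failed family is reported, the others proceed).
- **Inference.** The variance matrix is the inverse observed information,
  with the information computed by central differences of the analytic
  score (step 1e-5, symmetrized). Wald z = estimate/SE with two-sided normal
  p-values; no small-sample correction.

Degenerate inputs: rank-deficient designs raise a singular-information
error before optimization; linear predictors beyond |eta| = 50 are rejected
as overflow rather than clipped; responses must be non-negative integers.

## Model comparison

`AIC = -2 l + 2k`, `AICc = AIC + 2k(k+1)/(n-k-1)`, `BIC = -2 l + k ln n`,
with the dispersion parameter counted in `k` (13 Poisson, 14 NB2/GP under
the full council specification) and `n` passed explicitly so published
tables can be reproduced at their stated effective sample size. The Pearson
statistic uses each family's own variance function (`mu`, `mu + mu^2/alpha`,
`theta^2 mu`) over `df = n - k`. Ranking is by AIC, ties broken by BIC then
model name, and is invariant to input order.

One reporting subtlety worth stating prominently: published adequacy tables
of this design sometimes label the likelihood column "−2logL" while the
printed numbers are actually −logL (the AIC arithmetic `AIC = 2·value + 2k`
holds exactly). `information_criteria` takes a plain log-likelihood and is
agnostic to that labeling; the acceptance checks feed it the printed values
as −logL.

## Descriptive stage

Counts are binned into `[0,50]`, `[51,200]`, `[201, inf)` with labels
`"<50"`, `"51-200"`, `">200"`. The printed bin labels leave the value 50
unassigned; we place it in the first bin so the bins partition the
non-negative integers. Cell percentages are taken against the grand total
(not row totals). Independence is tested with the plain Pearson chi-square —
no Yates correction and no exact-test fallback even when expected cells fall
below 5 (a warning flag reports that condition); this convention reproduces
the published zone-table p-values 0.01106 and 0.00474 exactly to their
printed precision. A table with an empty row or column margin is degenerate
for the test; the pipeline then reports the cross-tab without a p-value.

## Synthetic data generator

The generator emulates the study design so every pipeline stage is testable
without the restricted health-system data: 184 councils; zone frequencies
(15, 24, 36, 31, 23, 32, 23)/184 and urban probability 45/184 from the
published margins; GP counts with `theta = 2` and the published GP
coefficient vector as the default truth on the design scale (log population,
log GDP). Each council's total is split into the two age-group counts as
independent GP draws with means `0.6·mu` and `0.4·mu` at the same `theta`;
the GP family is closed under convolution at equal `theta`, so the total
response remains exactly GP(`mu`, `theta`) and recovery tests against the
truth are exact, not approximate.

Covariate laws (the study publishes no covariate summary statistics; these
are plausible stand-ins chosen once, not reproductions):

| covariate      | law                         | default            | rationale |
|----------------|-----------------------------|--------------------|-----------|
| PPLHIV (%)     | Gamma(shape 2, scale 2.5)   | mean 5, sd 3.5     | right-skewed prevalence, a few high-burden councils |
| population     | log-normal(12, 0.8)         | median ≈ 163 k     | council populations spanning ~30 k to ~1 M |
| GDP            | log-normal(19.5, 0.9)       | arbitrary units    | only the log scale matters given the fixed coefficient |
| facilities     | round(Gamma(2, 25))         | mean 50, sd ≈ 35   | many small councils, a right tail of facility-dense urban ones |
| % male         | Normal(47, 8) clipped [0,100] | —                | roughly balanced sex mix |

Locations are set so that, with the published coefficients, the induced
counts look like the study's: majority of councils below 50, medians near
45, maxima around 10^3 (the published range is 0–958), pooled
variance/mean far above 1, strong positive skew. Counts go missing jointly
(both age groups) with probability 7/184, giving an effective complete-case
n near 177, the study's implied effective sample size.

What the generator does **not** emulate: the exact published
count-category margins (e.g. 24 of 184 councils above 200 in the 5–59
group). Under a log link with the published coefficient magnitudes, matching
that flat a mean distribution would require covariate tails that push a few
councils to implausible means (tens of thousands); the real data presumably
achieve it through covariate structure the publication does not report.
Passing tests therefore demonstrate correct inference under the assumed GP
data-generating process, not agreement with the restricted data's empirical
margins. There is also no spatial autocorrelation — zone effects enter only
through fixed-effect dummies — and no population-exposure offset, matching
the modelled-raw-counts design.

Sampling is by inversion of the cumulative GP pmf tabulated to cap
`mu + 50·theta·sqrt(mu) + 100` (exact to the cap; a uniform draw beyond the
tabulated mass raises instead of clipping). For `theta < 1` the support is
finite at the bound `m` and the truncated pmf is *not* renormalized,
matching the distribution's definition; the signed mass deviation is exposed
via `gp_mass_deficit` (it can be slightly above or below 1, within 1% for
the settings tested). All randomness flows through one integer seed into a
numpy PCG64 `Generator`; identical seeds give byte-identical datasets.

## Problem sizes used in the test and acceptance suites

Chosen as the smallest sizes at which the statistical claims are stable:
parameter recovery at n = 2000 (single fit, 3-SE check) and 200 replicates
of n = 500 for 95% Wald coverage; model-selection and SE-comparison claims
on 100 replicates of n = 1000 overdispersed councils (theta = 2); sampler
moments at n = 10^5. The acceptance script repeats the model-selection study
at 50 replicates.

## Known limitations

- Dispersion is a single scalar per model; no dispersion regression beyond
  the intercept, and no zero-inflated or hurdle variants.
- GP maximum-likelihood dispersion estimates are biased slightly downward in
  small samples (visible at n ≈ 180 with 14 parameters), as is usual for
  ML variance-type parameters; coverage statements are calibrated at
  n = 500+.
- Complete-case handling only; no imputation of missing counts.
- The Wald dispersion z-value tests `log(dispersion) = 0`, i.e. theta = 1
  (Poisson), which is a boundary-adjacent hypothesis; interpret with care.
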