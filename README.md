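# countdisp

Count-data regression for disease-incidence disparities across administrative
units, built around the generalized Poisson (GP) model. The package fits
maximum-likelihood Poisson, negative binomial (NB2), and GP log-link
regressions to council-level counts, compares their adequacy with information
criteria and the Pearson chi-square dispersion diagnostic, and runs the
descriptive association stage (count categorization, contingency tables,
chi-square independence tests) that typically precedes the modelling.

It is aimed at biostatisticians and epidemiologists analyzing routine
health-information-system counts — e.g. diabetes admissions per council —
where the counts are strongly overdispersed: many zeros and small values in
rural units, occasional very large values in urban ones.

## The models

For council $i$ with covariate vector $x_i$ and count $Y_i$, all three
families share the log link $\ln \mu_i = x_i^\top \beta$ and differ in their
variance:

| family  | pmf                                                                 | variance              |
|---------|---------------------------------------------------------------------|-----------------------|
| Poisson | $e^{-\mu}\mu^y / y!$                                                | $\mu$                 |
| NB2     | $\frac{\Gamma(\alpha+y)}{y!\,\Gamma(\alpha)} \left(\frac{\mu}{\alpha+\mu}\right)^y \left(\frac{\alpha}{\alpha+\mu}\right)^\alpha$ | $\mu + \mu^2/\alpha$ |
| GP      | $\mu\,[\mu+(\vartheta-1)y]^{\,y-1}\, \vartheta^{-y} e^{-[\mu+(\vartheta-1)y]/\vartheta} / y!$ | $\vartheta^2 \mu$     |

The GP dispersion factor $\vartheta$ makes the family flexible:
$\vartheta = 1$ recovers the Poisson exactly, $\vartheta > 1$ models
overdispersion, and $\vartheta < 1$ underdispersion (with a finite support
bound $m$, the largest integer with $\mu + m(\vartheta-1) > 0$). Dispersion
parameters are estimated on the log scale as one extra likelihood parameter,
so a GP or NB2 fit has $k = 14$ parameters against the Poisson's 13 under the
full council covariate specification (intercept, % people living with HIV,
log population, log GDP, number of health facilities, % male among cases,
urban dummy, and six zone dummies against the Northern reference).

Adequacy is compared with AIC ($-2\ell + 2k$), AICc, BIC, and the Pearson
ratio $\chi^2/\mathrm{df}$ computed with each family's own variance function;
a ratio far above one flags unabsorbed overdispersion.

Because the original council data are access-restricted, the package includes
a first-class synthetic generator (`countdisp.synthetic`) that reproduces the
study design: 184 councils, the published zone and residence frequencies,
right-skewed covariates, and GP counts with the published coefficient vector
as the default truth.

## Worked example

```sh
countdisp simulate --seed 11 --out councils.csv
countdisp analyze councils.csv --out report.json
countdisp compare report.json
```

prints the ranked adequacy table (184 synthetic councils, 180 complete cases
after missing-count drops):

```
  model      loglik  minus2loglik         aic        aicc         bic  pearson_chi2  df  pearson_ratio  n_used  k_params
     gp -707.750008   1415.500015 1443.500015 1446.045470 1488.201411    188.055231 166       1.132863     180        14
     nb -727.577588   1455.155175 1483.155175 1485.700630 1527.856571    211.802734 166       1.275920     180        14
poisson -812.780836   1625.561672 1651.561672 1653.754443 1693.070111    626.492461 167       3.751452     180        13
```

The GP model attains the smallest AIC/AICc/BIC, and its Pearson ratio (1.13)
is close to one while the Poisson's (3.75) reveals the overdispersion —
consistent with the generating truth $\vartheta = 2$ (variance ratio
$\vartheta^2 = 4$). Inside `report.json` the GP coefficient block recovers
the generator's truth; for example the urban effect (truth 1.1720):

```
Urban                 1.1587  0.0337  1.654e-259   # estimate, SE, p
```

and `data_summary` shows the raw overdispersion that motivates the GP model
(age 5–59 counts: mean 42.6, variance 2564, ratio 60.2, skewness 3.1).

The same analysis is available as a library:

```python
import countdisp as cd

records, truth = cd.generate(cd.default_config(seed=11))
report = cd.run_analysis(records)          # descriptives + 3 fits + ranking
report.comparison                          # the table above
report.fits["gp"].summary()                # Wald coefficient table
```

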