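# policyits

Interrupted-time-series (ITS) evaluation of maternal-health fee policies on
hierarchical birth-history data.

Many low-income countries removed or subsidised delivery fees in the 2000s;
the canonical evaluation question is whether facility-delivery rates rose
— and neonatal mortality fell — *beyond their secular trends* when the
policy started, and whether the change persisted.  With a national policy
there is no control group, so the design is a segmented regression on
retrospective birth histories of the DHS type: one row per live birth,
nested in women, households, survey clusters and regions.  `policyits` is
for epidemiologists and health-policy analysts who want that full analysis
— cohort simulation, model fitting, and population-standardized effect
grids — as tested, reusable Python.

## The model

For birth *i* of woman *j* in cluster *k*, a log-link Poisson model on the
binary outcome ("modified Poisson", so coefficients exponentiate to rate
ratios) with segmented time effects and random coefficients:

    log E[Y_ijk] = (β₀ + γ₀jk + γ₀₀k) + (β₁ + γ₁k) T_ijk
                   + (β₂ + γ₂k) I_ijk + (β₃ + γ₃k) post_time_ijk
                   + β₄ rural_k + β₅ SES_jk + β₆ Educ_jk + β₁₀' X_ijk

β₁ is the secular trend, β₂ the immediate level change at the policy
cutoff, β₃ the slope change after it; γ terms are cluster- (and woman-)
level random effects with covariance Ψ.  The marginal likelihood is
maximised with adaptive Gauss–Hermite quadrature; standard errors are
region-clustered sandwich estimates.  Model-based standardization
(g-computation) then averages each birth's counterfactual predictions —
subsidy on vs off, at horizons 0–42 months, empirical-Bayes random effects
included — into marginal rate ratios (RR) and rate differences (RD) with
delta-method CIs.  Three exposure definitions handle the uncertain
roll-out date: official January-2007 cutoff, April-2007 shift, and
exclusion of the indeterminate first quarter.

Because the underlying survey microdata is registration-gated, the package
includes a first-class synthetic-cohort generator matching the survey's
hierarchy and covariate margins; all machinery is validated against
generator truth (see `docs/methods.md`).

## Worked example

```python
from policyits import (PopulationConfig, generate_population,
                       ExposureScenario, apply_scenario, collapse_deliveries,
                       ModelSpec, MultilevelPoissonITS, standardize)

cfg = PopulationConfig(n_clusters=150, households_per_cluster_mean=10.0,
                       seed=1)
records, truth = generate_population(cfg)

scenario = ExposureScenario.primary()          # exposed from January 2007
births, _ = apply_scenario(records, scenario)
deliveries = collapse_deliveries(births[births.birth_month >= 72])

spec = ModelSpec(outcome="delivery", random_terms=("intercept",),
                 fixed_terms=("time", "subsidy", "post_time", "rural",
                              "wealth", "literacy"))
result = MultilevelPoissonITS.from_records(deliveries, spec, scenario).fit()
print(result.summary())
print(standardize(result, horizons=(0, 12, 24, 42)).to_text())
```

prints

```
Multilevel Poisson ITS (delivery, scenario=primary)
births=2529  clusters=150  regions=13  loglik=-2189.713  converged=True
term                          coef        se       p
intercept                  -0.5239    0.1918   0.006
time                       -0.0089    0.0086   0.301
subsidy                     0.1353    0.0637   0.034
post_time                   0.0119    0.0088   0.175
rural                      -0.2134    0.1341   0.111
wealth:poorer               0.0849    0.0497   0.088
wealth:middle               0.2019    0.0641   0.002
wealth:richer               0.1440    0.0490   0.003
wealth:richest              0.1486    0.0654   0.023
illiterate                 -0.0942    0.0464   0.042
Random parts (cluster level):
  psi_intercept       0.1984

Standardized effects (delivery, primary)
   h               RR (95% CI)                   RD (95% CI)
   0          1.14 (1.01-1.30)        +6.9% (+0.8 to +12.9%)
  12          1.32 (0.96-1.81)       +13.6% (+0.1 to +27.1%)
  24          1.52 (0.91-2.56)       +20.0% (+0.1 to +39.9%)
  42          1.89 (0.82-4.31)       +28.8% (+1.6 to +56.0%)
```

Reading: the cohort was generated with an immediate subsidy effect of
β₂ ≈ 0.14 on the log-rate scale; the fit recovers 0.135 (robust SE 0.064),
i.e. an immediate ~14% rise in facility deliveries (RR 1.14 at horizon 0),
with the standardized effect growing along the fitted slope change and the
CI widening as the projection extends.  `truth` carries the generating
parameters for exactly this kind of comparison.

The same workflow runs from the shell: `policyits simulate`, `describe`,
`fit`, `standardize`, `report` (full 2-outcome × 3-scenario pipeline) and
`recover` (simulation-recovery harness); see `policyits --help`.

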