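# Methods

## Problem and design

`policyits` evaluates a nation-wide delivery-fee subsidy (Burkina Faso,
introduced January 2007 with a 0–3 month district roll-out) on two binary
perinatal outcomes — facility delivery and neonatal death (death within the
first 28 days of life) — using an interrupted-time-series (ITS, segmented
regression) design on retrospective birth histories of the DHS type.  With
a national policy there is no concurrent control group; identification
rests on modelling the secular trend and the level/slope changes at the
cutoff.

The analysis unit is the live birth, nested in women/households, in survey
clusters (enumeration areas), in regions.  Because the actual survey
microdata is registration-gated, the package ships a first-class synthetic
cohort generator that reproduces the survey's structure and margins; every
stage of the machinery is validated against generator truth.

## The model

For birth *i* of woman *j* in cluster *k*,

    log E[Y_ijk] = (b0 + g0_jk + g00_k) + (b1 + g1_k) T_ijk
                   + (b2 + g2_k) I_ijk + (b3 + g3_k) post_time_ijk
                   + b4 rural_k + b5 SES_jk + b6 Educ_jk
                   + interactions + b10' X_ijk

* `T` — months since the observation origin (June 2005 for the delivery
  outcome, January 2000 for mortality); `b1` is the secular trend.
* `I` — subsidy exposure (1 from the cutoff month inclusive); `b2` is the
  immediate level change.
* `post_time` — months since the cutoff, 0 before; `b3` is the slope
  change.
* `g00_k, g1_k, g2_k, g3_k` — cluster-level random intercept and
  coefficients with covariance Ψ; `g0_jk` — woman-level random intercept
  (3-level models).
* `X` — maternal age group (5-year bands, 40–49 merged), multiple birth,
  birth order, preceding birth interval, newborn sex, maternal occupation.
  Reference categories: literate, poorest quintile, single birth, age
  15–19, first birth, not working, January.

A Poisson likelihood with log link is used on the binary outcome (the
"modified Poisson" device) so exponentiated coefficients are rate ratios;
the mis-specified variance is repaired by region-clustered sandwich
standard errors.  Education (none/primary/secondary+) and literacy are
never entered together — they are nearly collinear — and the preceding
interval enters only through its short-interval (<36 months) contrast,
because its "first birth" level is exactly the birth-order reference.

## Estimation

The marginal likelihood integrates the random effects out:

* **Cluster effects (up to 3 dimensions):** adaptive Gauss–Hermite
  quadrature.  Each cluster's integrand is re-centred at its posterior mode
  (found by a damped, fully vectorised Newton iteration; the integrand is
  concave) and scaled by the local curvature.  Default 7 nodes per
  dimension (5 for ≥2 dimensions in the pipeline defaults); one node
  recovers the Laplace approximation.  On toy problems the quadrature
  agrees with wide-grid trapezoid integration to <1e-6.
* **Woman-level intercept (3-level models):** a prior-scaled Gauss–Hermite
  rule nested inside the cluster rule.  Conditional sample sizes per woman
  are ≤8 births, where a prior-scaled rule is adequate; with the woman
  variance →0 it agrees with the 2-level likelihood to <1e-6.
* **Birth-level frailty (over-dispersion screen only):** a 9-node rule per
  birth, with analytic first/second derivatives used inside the Newton
  mode-finder.

Ψ is parameterised by a log-Cholesky factor (unstructured by default,
diagonal on request), which enforces positive semi-definiteness.  The
optimizer is L-BFGS-B with numerical gradients; the fixed-effect block is
preconditioned by the Cholesky factor of the IRLS information matrix so the
months-scaled time columns do not ill-condition the search (this cut
typical fit times by an order of magnitude and removed convergence
failures).  Log-SD parameters are bounded in [-7, 3]: a vanishing variance
hits a clean boundary instead of drifting on a flat ridge at −∞.  Any
random term whose fitted SD falls below 0.01 is removed and the model
refitted (flagged in the results) — reproducing the collapse to a simple
Poisson regression when clusters show no variance.  Extra random restarts
(jittered variance parameters) engage when the principled start fails;
with all variance components zero the fit is an exact Newton–Raphson IRLS
and matches an independent GLM implementation to machine precision.

Convergence tolerance is 1e-9 on the relative log-likelihood change, well
below the sampling precision of any reported coefficient.

### Inference

* Model-based covariance: inverse of a central-difference observed
  information over all parameters.
* Robust covariance: sandwich with scores summed within regions (numerical
  per-cluster score Jacobian), with a G/(G−1) small-sample factor
  (G = number of regions; the factor can be disabled, e.g. to compare with
  textbook HC0).
* Likelihood-ratio tests for interactions, random terms and hierarchy; a
  variance component tested on its boundary uses the 50:50 χ²(0):χ²(1)
  mixture.
* Empirical-Bayes prediction: posterior modes of the cluster effects (for
  3-level fits, quadrature posterior means at cluster level and
  conditional modes for the woman intercepts).  Collapsed terms predict 0.
* Multicollinearity screen: VIFs on the fixed design (intercept,
  interactions, seasonal dummies excluded).  Confounder/seasonality
  screens: keep a term if it moves the subsidy coefficient by ≥10%
  (indeterminate, hence kept, when the reference coefficient is 0).
* Over-dispersion screen: boundary LRT of a birth-level log-normal
  frailty.  On a binary outcome only P(Y=1|x) is observable, so a
  mean-preserving birth-level frailty is not identifiable through the
  Poisson working likelihood: the screen correctly drives the frailty
  variance to its boundary (statistic 0) both on clean Bernoulli data and
  on data generated with injected frailty.  The screen is therefore a
  specification safeguard — it can flag genuine count-like
  over-dispersion, and its null behaviour is verified — but it has no
  power against latent frailty in binary outcomes.

## Standardization (g-computation)

For horizons h = 0, 6, …, 42 months after the cutoff, each birth's rate is
predicted under subsidy-present and subsidy-absent scenarios with
`T = (cutoff − origin) + h` and `post_time = h·I` — the population is
standardized to the policy timeline (the per-birth-calendar alternative is
available via `time_basis="cohort"`).  Predictions include each record's
empirical-Bayes random-effect values and are capped at 1 (capped fractions
are reported; >1% carries a warning).  RR is the ratio and RD the
difference of the two population means.  Confidence intervals come from
the delta method over the fixed effects only (central differences, step
1e-5·max(1,|b|)), on the log scale for RR; the robust covariance is used by
default.  Uncertainty in Ψ and in the EB predictions is not propagated —
a documented limitation shared with the delta-method-on-predictions
approach the design follows; measured coverage of the 95% RR interval at
the default study conditions is ≈95/100.

## Exposure scenarios

* `primary` — exposed from January 2007 (month-resolution data cannot split
  the cutoff month, so the cutoff month itself is exposed).
* `shift_april` — exposed from April 2007 (the latest roll-out date).
* `exclude_q1` — January cutoff, births of January–March 2007 dropped as
  indeterminate and reported separately.

Generated data carries the *true* staggered cluster-level exposure;
analysing it with the sharp January cutoff misclassifies early-2007 births
in late-adopting clusters and measurably attenuates the estimated
immediate effect relative to an oracle analysis using true exposure — the
rationale for the sensitivity scenarios, and a standing simulation in
`recovery.run_attenuation`.

## Synthetic cohort generator

Defaults emulate the 2010 survey frame: 13 regions, 550 clusters
(20.7% urban), ~15 responding households per cluster, 1.25 women per
household, 1–8 births per woman (truncated negative binomial, median 3),
~32,000 live births over January 2000–December 2010, twins at 1.78% of
deliveries (3.5% of births).  Covariate margins follow the published
descriptive table (79.3% rural, 87.9% illiterate, wealth quintiles, age
bands, interval categories).  Outcomes are drawn from the log-rate model
above with published-scale coefficients (delivery: urban intercept −0.54,
rural −0.38, subsidy 0.039 urban / 0.139 rural, wealth gradients;
mortality: ~3.9% pre-period rate falling to ~2.6%) and cluster effects
with ψ11 = 0.7682, ψ22 = 0.0819 and an intercept–subsidy correlation of
−0.9 (low-baseline clusters gain most; −1 is representable as a
rank-deficient PSD matrix).

Design notes and known deviations:

* **Log-link truncation.** A log-link Bernoulli model with baseline rates
  of 0.4–0.6 and intercept SD ≈0.88 implies rates >1 for a sizeable share
  of births; rates are truncated at 1−1e-9 before the Bernoulli draw, the
  count is recorded in the truth sidecar, and a warning fires above 1%.
  This is an inherent incompatibility of the published modified-Poisson
  scale with a generative Bernoulli model, not an implementation artefact.
  Truncation compresses realized cluster heterogeneity, so fitted ψ
  diagonals sit ~20% below the configured values even for a correctly
  specified fit (an independent mixed-model implementation reproduces the
  same estimates on exported data).
* **Random time-slope variance.** The published ψ33 (0.0044) at a monthly
  time scale implies log-rate spreads of ±4 over the observation window
  and near-total truncation; the generator defaults use 5e-5 (delivery)
  and 1e-5 (mortality), keeping visible cluster-level trend heterogeneity
  without degenerate rates.
* **Ages and intervals are emergent.** A woman's age at each birth derives
  from a drawn age at first lifetime birth, prior parity (≈50% of women
  have pre-window births) and the drawn inter-birth gaps, which enforces
  within-woman age monotonicity; long gaps are drawn at inflated odds to
  offset window compression for high-parity women.  Age and interval
  margins therefore match the targets only to ~±0.05 absolute, while the
  directly sampled covariates match within binomial error.
* **Variance components on binary data are attenuated.**  Under the
  Poisson working likelihood on Bernoulli outcomes, random-slope variances
  are systematically under-estimated unless clusters are large; the
  boundary-LRT power study uses ~90-birth clusters for that reason.
* Seasonality (flat by default) modulates each woman's first birth month;
  no survey weights, no stillbirths, no maternal deaths, no interview-date
  structure.  What passes on this generator shows the machinery is
  correct under the stated model — not that the model is correct for any
  real survey.

## Problem sizes used in the shipped studies

The standing studies run at reduced, fixed scales chosen to give stable
Monte-Carlo summaries: parameter recovery at 250 clusters (~12,000 births,
10 replicates; reduced covariate-free segmented model with a cluster random
intercept), ψ recovery at 100 clusters with a correlated random subsidy
slope, CI coverage on 100 replicates of 60 clusters, attenuation at 150
clusters with a 3-month roll-out, and the pipeline demonstration at 150
clusters.  The acceptance script re-runs all of them from scratch.

## Known limitations

* The published coefficient and RR/RD tables cannot be reproduced
  numerically without the gated survey data; the package reproduces the
  published *descriptive* arithmetic exactly and validates all machinery
  against generator truth instead.
* Delta-method CIs ignore Ψ/EB uncertainty (see above).
* The 3-level likelihood uses a prior-scaled (not mode-adaptive) cluster
  rule; accuracy was verified against the 2-level adaptive rule in the
  vanishing-variance limit, but very large clusters with strong effects
  would warrant mode adaptation there too.
* DHS sampling weights and the two-stage design are intentionally out of
  scope; wealth quintiles are consumed as given covariates.
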