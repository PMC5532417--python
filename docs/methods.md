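# Methods

## Model

The package implements arm-based Bayesian evidence synthesis for a
connected network of treatments. For trial `i` with arms `k` and
reference arm `ref(i)` (placebo when the trial has one, otherwise the
lowest-ordered drug in the fixed order placebo, GXR, LDX, ATX, MPH-ER,
MPH-IR), the linear predictor is

    theta_ik = mu_i                                       k = ref(i)
    theta_ik = mu_i + delta_ik + sum_m beta_m x_im^c      otherwise

with a normal/identity likelihood for score change (`y_ik` the observed
mean change, `se_ik` its reported standard error) and a binomial/logit
likelihood for event counts. Continuous arm data are always a
(mean change, SE) pair; arm SDs are never required. Zero event counts
need no continuity correction — the binomial likelihood handles them
natively (the 1/2 correction appears only in the classical pairwise
Q/I^2 computation, and only when a zero cell occurs).

Under fixed effects `delta_ik = d_k - d_ref(i)`; under random effects the
per-trial vector of contrasts is multivariate normal around those
consistency contrasts with between-trial SD `tau` and correlation 1/2
between the contrasts of a multi-arm trial (covariance `tau^2 / 2`
off-diagonal). Basic parameters are all relative to placebo
(`d_placebo = 0`); trials without a placebo arm contribute through the
consistency relation `d_AB = d_B - d_A`.

Meta-regression coefficients are shared across treatments: one
coefficient per covariate applied to every active-vs-reference contrast.
A per-treatment interaction model would be identifiable only for the
best-populated comparisons here, and nothing in the reporting conventions
this package mirrors suggests treatment-specific adjustment; the shared
coefficient is the package's design choice. Covariates are centered at
their across-trial grand means weighted by each trial's total randomized
patients in the included arms (the plausible alternative — weighting by
arm within outcome network — changes the centering constant only, which
is absorbed by `mu_i` and leaves contrasts unchanged).

## Priors

Location parameters (`mu`, `d`, `beta`) get `Normal(0, 100^2)`; `tau`
gets `Uniform(0, U)` with `U = 50` on the score scale and `10` on the
logit scale. These are wide relative to everything observable in this
domain (|d| <= ~15 score points, |log OR| <= ~2.2), i.e. effectively
non-informative, and are exposed via `PriorSpec`.

## Sampler

A self-contained blocked MCMC sampler (`run_mcmc`) with per-chain RNG
streams spawned from a master seed; identical seeds give byte-identical
draws, and chains are independent of how many run.

* Normal model: every location block is conjugate and updated exactly —
  `mu` jointly across trials, `delta` per trial (small MVN solves),
  `d` by generalized least squares against the trial effects with the
  block correlation structure, `beta` by weighted regression. Under
  fixed effects `(d, beta)` are drawn as one joint Gaussian block.
* Binomial model: univariate slice sampling (stepping-out with
  shrinkage) for `mu`, the trial effects and `beta`; step widths adapt
  during burn-in via an exponential moving average of accepted moves and
  are frozen when burn-in ends, so retained draws come from a fixed
  kernel. Given the trial effects, `d` remains conjugate (it enters only
  the trial-effect prior) and keeps its exact GLS update.
* `tau`: after collapsing the per-trial quadratic forms, the full
  conditional is a cheap one-dimensional density sampled by slice on
  `(0, U]`.

Slice sampling accepts by construction, so no Metropolis acceptance-rate
warning is applicable; the sampler's health is monitored through the
convergence diagnostics instead.

Per-draw deviance (-2 log likelihood, all normalizing constants
included) is recorded alongside the draws. The DIC plug-in `D_hat` is
evaluated at component-wise posterior means of the location parameters;
since the linear predictor is linear in all of them, this equals the
deviance at the posterior-mean linear predictors — the convention that
keeps `p_D` stable under reparameterization of the logit model.

The default iteration profile is 50,000 burn-in + 50,000 retained
iterations on 2 chains. A reduced profile (2,000 + 4,000) is provided for
desk-scale work; the test suite and the property checks below use
500-3,000 retained draws per fit, sizes at which the conjugate normal
sampler's Monte-Carlo error on posterior means is well under a tenth of a
posterior SD.

## Reporting

Credible intervals are equal-tailed empirical percentiles (2.5/97.5 for
95%) with linear interpolation between order statistics — the
interpolation rule only matters at small draw counts. Posterior point
estimates are means (of the mean difference, and of the OR on the OR
scale). Relative risks convert odds ratios with the pooled placebo risk
`p0` (event total over patient total across placebo arms):
`RR = OR / (1 - p0 + p0 OR)`. For RR credible intervals, `p0` is drawn
once per retained iteration from its Jeffreys sampling distribution
`Beta(r + 1/2, n - r + 1/2)`, propagating placebo-rate uncertainty; the
tabulated RR point estimate converts the posterior-mean OR at the pooled
point estimate, which reproduces published-style tables from their
printed ORs to 2 decimals (occasionally off by 0.01, since published
tables summarize unrounded posteriors; both per-draw mean and median RR
are also reported). Absolute rates are `RR * p0`, clipped at 1 with a
warning. The pooled risk's own 95% CI uses the Wilson method by default.

`P(best)` counts, per retained draw, which treatment attains the most
favourable effect (most negative mean difference; largest response
effect; smallest discontinuation effect); exact ties split their weight
equally — ties are measure-zero for real posteriors, but degenerate
synthetic inputs need a fixed rule. Pairwise superiority probabilities
use the same tie rule, so `P(a beats a) = 0.5`.

## Heterogeneity and convergence diagnostics

Pairwise heterogeneity is classical two-treatment meta-analysis over the
trials directly comparing a pair: inverse-variance pooling of per-trial
contrasts (mean difference with variance `se_a^2 + se_b^2`, or log odds
ratio with the reciprocal-cell variance), Cochran's Q against chi-square
with k-1 df, `I^2 = max(0, (Q - df)/Q)`. The I^2 confidence interval is
the test-based (Higgins-Thompson) interval via `ln H`; it is suppressed
for pairs informed by fewer than three trials, where the approximation
has no support. Pairs compared in fewer than two trials are reported as
not computable.

Geweke compares the means of the first 10% and last 50% of a chain,
standardized by spectral densities at frequency zero estimated from
autoregressive fits with AIC order selection (orders up to
min(20, n/10)). Heidelberger-Welch applies the Cramer-von Mises test to
the Brownian bridge of cumulative sums, discarding leading 10% increments
until it passes or half the chain is gone; the spectral variance in the
bridge is estimated from the second half of the segment so early
non-stationarity cannot mask itself. The half-width test compares
`z_{0.975} * sqrt(s0/n)` to `eps * |mean|`; when the mean is not resolved
from zero at that precision the ratio is reported as not applicable
rather than failed.

## Synthetic data generator

`mtcnma.synthetic` emits arm-level networks from exactly the generative
structure the random-effects model assumes, with all latent values
returned as ground truth. The default configuration encodes the published
evidence base: a 42-entry roster whose per-outcome memberships give 20
trials for score change (no MPH-IR node), 14 core + 6 short-term trials
for CGI-I response, 31 for all-cause discontinuation (including one
trial missing age/sex that only the unadjusted sensitivity analyses can
use) and 32 for AE-related discontinuation; drug-trial counts 6 GXR /
4 LDX / 21 ATX / 10 MPH-ER / 6 MPH-IR with the published head-to-head
multiset (one GXR+ATX three-arm trial, four ATX+MPH-ER trials, three
MPH-ER+MPH-IR trials, etc., two of the ATX-vs-MPH-ER trials without a
placebo arm); arm sizes uniform on 16-222; mean age 8.5-14.6 years,
percent female 9.4-36.1, baseline ADHD-RS-IV 31.5-43.5, double-blind
durations 3-16 weeks (short-term trials at <= 3 weeks).

True basic parameters default to the published point estimates (score
differences -8.68/-14.98/-6.88/-9.33; binary effects the log of the
printed odds ratios), binary placebo baselines to logit of 0.31 / 0.28 /
0.02. Choices the published record does not pin down, made once:

* between-trial SD `tau` = 1.5 score points (continuous; moderate
  heterogeneity relative to effects of 7-15 points) and 0.3 log-odds
  (binary);
* reference-arm linear predictors `mu_i ~ Normal(-9, 3)` on the score
  scale (typical placebo improvement) and `Normal(logit p0, 0.4)` on the
  logit scale;
* within-arm SD of individual score changes 13 points, so reported arm
  SEs are `13/sqrt(n)` — consistent with arm SDs around 12-13 in this
  literature;
* covariate coefficients default to zero: the published record reports
  no residual covariate signal after adjustment, and a zero default
  keeps generator truth and model estimand aligned regardless of the
  centering convention. Non-zero coefficients are exercised in unit
  tests.

What the generator does **not** emulate: reporting heterogeneity
(different scales and imputation schemes across trials), correlated
outcomes within a trial (each outcome is simulated independently),
dose-response structure within a pooled treatment node, non-uniform
covariate distributions, or publication/small-study bias. Passing the
recovery and calibration suites therefore shows the pipeline is correct
for data satisfying the model's assumptions, not that those assumptions
hold for any particular real extraction.

## Analysis matrix and pipeline

The core analysis for every outcome is the random-effects model adjusted
for mean age and percent female, excluding short-term (<= 3 week) trials.
Sensitivities: fixed-effects adjusted, random and fixed unadjusted (all
outcomes); random and fixed adding baseline ADHD-RS-IV (continuous
outcome, at the cost of trials that do not report it); random and fixed
admitting short-term trials (CGI-I response) — 6/6/4/4 variants including
the core. A per-variant treatment-label override supports reclassifying
an imputed MPH-ER trial as MPH-IR. Trials missing a required covariate
drop out of adjusted variants only; a trial enters only the outcome
networks it reports.

Per-variant seeds are `sha256(master_seed, label) mod 2^31`, so adding or
removing variants never perturbs the others and the full pipeline is
byte-reproducible for a fixed master seed (verified file-for-file in the
test suite). A failing sensitivity variant is recorded in the report and
the remaining variants still run; a disconnected core network (checked
against the GXR and ATX anchors) is a hard error.

## Numerical notes and limitations

* Degenerate tie-handling rules (prob-best, pairwise) are fixed and
  documented above. Quantile interpolation is linear.
* The Gibbs sampler mixes poorly if `tau` is pinned essentially to zero
  by its prior bound (the trial effects then random-walk with step
  `tau`); the fixed-effects model is the correct way to impose `tau = 0`.
  The tau-to-zero agreement test therefore pins the bound at 0.2, small
  against posterior SDs of ~1.3 but large enough to mix.
* DIC's `p_D` can be slightly negative under heavy posterior skew; it is
  flagged, not fatal.
* Two dose arms of the same drug in one trial are pooled before modeling
  (counts summed; means and SEs combined by inverse variance); modeling
  dose arms separately within a treatment node is out of scope.
* No inconsistency (node-splitting) models, no SUCRA beyond P(best), no
  informative priors, no dose-response or class-effect structure.
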