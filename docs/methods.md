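# Methods

This note documents the statistical model behind `rdipw`, the synthetic
cohort generator and its defaults, the numerical choices, and the known
limitations. It is written for someone who wants to judge what the
package's passing tests do and do not demonstrate.

## Discrete-time hazard framework

All estimators operate on a person-period expansion: subject *i* contributes
one row per period *t* (default one month) from entry until death, and the
per-period death indicator is modelled by a binomial GLM. The default link
is the complementary log-log,

    cloglog P(event in t | at risk, x) = α(t) + β'x,

under which β is a log hazard ratio invariant to the period length; a logit
link is offered because a "hazard ratio" reported from a discrete-time model
may in fact be an odds ratio, and the link used is recorded in every fit's
metadata. Period main effects α(t) enter as a restricted cubic spline in
the period index (4 knots at evenly spaced quantiles) rather than one
indicator per period; with very few distinct periods the basis degrades
gracefully to indicators. This keeps narrow-bandwidth fits stable at the
cost of assuming a smooth baseline hazard in time.

Person-time is conserved exactly by the expansion (tested to 1e-9), events
can only occupy a subject's final row, and administrative (lab-gap)
censoring only removes trailing rows.

## Fuzzy regression discontinuity

Eligibility is assigned strictly below the CD4 threshold (a count exactly
at 200 cells/μL is ineligible, matching a "dropped below 200" rule; the
threshold itself is configurable). The ITT model regresses the event
indicator on eligibility, separate linear CD4-gap slopes above and below
the threshold, optional functional-form extensions (a squared
below-threshold term, or a restricted cubic spline in CD4 with an interior
knot at 125 cells/μL and boundary knots at the window edges), optional
baseline covariates, and the period spline. Bandwidth windows are inclusive
on both endpoints. The eligibility hazard ratio and a Wald CI are read off
the fitted coefficient.

The first stage summarises the design's strength: side-specific linear
probability fits of 6-month ART uptake against the centred CD4 count,
evaluated at the threshold, with an HC0 variance on the jump.

The CACE instruments current treatment status with eligibility. The
default estimator is maximum likelihood of the ivprobit system — a linear
first stage for treatment with normal errors, a probit outcome equation,
and correlated errors — optimised by BFGS with an analytic gradient and a
finite-difference Hessian for standard errors. Because the probit
coefficient is not itself a hazard ratio, it is mapped to the hazard-ratio
scale as the ratio of implied per-period event probabilities at the
covariate means; this conversion is one defensible choice among several
and is flagged in the fit's `method_used_`. A two-stage
residual-inclusion (2SRI) estimator with the requested GLM link is
available directly (`method="2sri"`) and is the automatic fallback when ML
does not converge. When treatment coincides exactly with eligibility
(sharp design) the instrumented model is the ITT model with a renamed
regressor, and the fit collapses onto it — point estimates agree to
machine precision, which the tests assert at 1e-6.

A weak first stage (jump CI covering zero) attaches a warning to the fit
rather than refusing it. The density-continuity diagnostic compares counts
in the two bins adjacent to the threshold with a Wilson binomial interval
mapped to the ratio scale; an empty adjacent bin is reported as
inconclusive rather than as evidence either way.

## Inverse probability weighting

Treatment is absorbing (no discontinuation is modelled). The time-invariant
contrast is "initiated within a 3-month grace period of entry" vs not.
Baseline stabilized weights use a marginal numerator and a logistic
denominator in the baseline covariates: age, sex, baseline CD4, education,
wealth quintile, distance to clinic, and residence. Missing covariate
values form an explicit "missing" category — no rows are dropped. Because
the assignment rule is a step in CD4, the propensity model includes a
below-threshold indicator alongside the linear CD4 term; omitting it would
misspecify the treatment model by construction. Weight truncation is off
by default, with optional symmetric percentile truncation for robustness
checks.

Time-varying treatment weights are cumulative products over the periods
before initiation of the ratio P(observed status | baseline covariates) /
P(observed status | baseline covariates + most recent recorded CD4 carried
forward); after initiation treatment is deterministic and the contribution
is one. Censoring weights have the same cumulative form for remaining
uncensored under the 12-month lab-gap rule. The exact covariate sets of
the time-varying models are a standard reconstruction (the motivating
analysis's full specification is not available) and are configurable
through `WeightModelSpec`.

The weighted MSM is unadjusted in the time-invariant case and conditional
on the baseline covariates in the time-varying case; the treatment × years
interaction model reports a per-year multiplicative change in the hazard
ratio. All weighted fits use a subject-clustered sandwich variance, since
weighting induces within-subject dependence; its calibration is verified
empirically by the null-coverage study rather than assumed. Time-invariant
analyses are never lab-gap censored.

## The synthetic cohort generator

The generator emulates a threshold-assigned HIV treatment cohort. Default
parameter values and what they represent:

| parameter | default | meaning |
|---|---|---|
| `n_subjects` | 4,435 | study-scale cohort |
| `threshold` | 200 cells/μL | eligibility threshold |
| `cd4_min`, `cd4_max` | 0, 350 | assignment-variable support |
| `eligible_fraction` | 2751/4435 ≈ 0.620 | share below the threshold |
| `p_init_below` / `p_init_above` | 0.85 / 0.05 | immediate-uptake probabilities |
| `late_init_hazard` | 0.03 /period | deferred initiation among initial non-initiators |
| `true_log_hr` | log 0.5 | conditional treatment effect |
| `hazard_scale` | 0.018 /month | event rate at CD4 = 0 |
| `hazard_cd4_slope` | −0.0075 /cell | log-rate gradient in CD4 |
| `n_periods`, `period_length` | 48, 1 month | follow-up horizon |
| `lab_interval`, `p_lab_miss` | 6 months, 0.25 | monitoring schedule and misses |
| `dropout_rate` | 0.004 /month | absorbing disengagement from lab monitoring |
| `n_assets` | 32 | binary asset battery for the PCA wealth index |

Baseline CD4 is drawn from a mixture of a uniform on [0, 350] and a
decreasing triangular with mode at 0; the mixture weight is solved
analytically from `eligible_fraction`, and the density is continuous
everywhere — in particular at the threshold, so the continuity diagnostic
should pass on clean draws (verified over 100 seeds). The recorded
0.1-cell CD4 value is the assignment variable throughout: eligibility,
uptake and hazard all use the same recorded value.

Treatment response uses a single uniform draw per subject shared between
the two counterfactual assignments, so compliance classes (always-taker /
complier / never-taker) are well defined and monotone by construction —
defiers cannot occur, and configurations with `p_init_below <
p_init_above` are rejected. Deferred initiation follows a constant
per-period hazard, mimicking return at a later monitoring visit.

The mortality hazard is driven by the *baseline* CD4 count (the assignment
variable) times the treatment effect, through the cloglog link:
`p_t = 1 − exp(−rate(cd4) · exp(β_t A_t))` with `β_t = true_log_hr +
trend_per_year · years`. With the default scale and slope the cohort shows
roughly 6.3 vs 2.5 deaths per 100 person-years below vs above the
threshold and about 4.5 overall, the magnitude a programme cohort of this
kind displays. Low CD4 therefore drives both treatment and death — the
confounding-by-indication structure that makes the unadjusted hazard ratio
come out harmful (≈ 1.4–1.8) while the true conditional effect is 0.5.
The only discontinuity at the threshold is in treatment probability; all
potential-outcome parameters are continuous in CD4.

A CD4 *trajectory* (linear decline of 4 cells/month off ART, recovery of
8 cells/month on ART) feeds the laboratory stream only: 6-monthly
scheduled visits, per-visit misses (optionally CD4-dependent via
`lab_miss_cd4_slope`), and absorbing disengagement from care (optionally
CD4-dependent). Mortality follow-up continues to the administrative end
regardless of disengagement, emulating population-surveillance outcome
ascertainment — so the time-invariant, uncensored analysis sees
near-complete mortality while the time-varying analysis is exposed to
lab-gap censoring.

Covariates are drawn to resemble a rural Southern-African programme
cohort: age ≈ N(34.5, 9.5) truncated to 16–80; sex female with probability
rising mildly in CD4 (≈ 65% below vs 76% above the threshold); education
in three bands (34/57/9%) with 2% missing; residence rural/periurban/urban
(52/37/11%) with 10% missing; clinic distance Gamma(2, 1.55) km (median
≈ 2.6 km); and 32 Bernoulli assets loaded on a latent wealth factor, with
10% of subjects missing the battery. The wealth quintile is the quintile
bin of the first principal component of the asset matrix, computed via the
empirical CDF of the score so tied scores share a bin.

### What the generator does not emulate

No outcome misclassification (verbal-autopsy error), no migration, no
clinic-level clustering, no calendar time, no measurement error in CD4
beyond 0.1-cell rounding, and no treatment discontinuation. The CD4
marginals match the motivating cohort only coarsely (the eligible-group
median lands near 95 rather than 101 cells/μL). Passing recovery tests
therefore show that the estimators are correct *under their own
assumptions*, not that those assumptions hold in any real cohort.

## Validation studies and problem sizes

The studies in `rdipw.validation` (reused by `scripts/acceptance.py`):

* **Sign reversal** — 50 cohorts of n = 2,000 under defaults: mean
  unadjusted log HR positive, mean baseline-weight MSM log HR negative.
* **Recovery** — 100 cohorts of n = 5,000 under `recovery_config`: uptake
  0.9/0.1 (first-stage jump 0.8) and *no* deferred initiation, so the
  control arm never crosses over and "immediate vs never" coincides with
  the conditional effect; the 2SRI CACE and the baseline-weight MSM means
  must land within ±0.1 of log 0.5. With crossover the time-invariant
  contrast itself is diluted (the default-config MSM lands near HR 0.75),
  which is a property of the estimand, not an estimator failure.
* **Null calibration** — 200 cohorts of n = 2,000 with true HR 1: the ITT
  (150–250 window) and MSM 95% CIs must cover 1 in 90–99% of replicates.

These sizes keep a full validation run to a few minutes on one CPU while
leaving Monte Carlo error well inside the asserted tolerances.

## Numerical choices

* GLM fits: statsmodels IRLS, maxiter 200; non-convergence or any
  coefficient beyond ±30 raises a separation error advising a wider
  bandwidth rather than returning a degenerate fit.
* Positivity: fitted treatment/censoring probabilities outside
  (1e−6, 1 − 1e−6) raise an error listing offending strata.
* ivprobit ML: starting values from OLS first stage and an exogenous
  probit; convergence declared at a mean gradient below 1e−4 per
  observation; ρ parameterised as tanh and σ on the log scale.
* Ties: subjects exactly at a bandwidth endpoint are included; CD4 exactly
  at the threshold is above-threshold (ineligible); a binned summary puts
  a count at the threshold in the bin starting there.
* Confidence intervals are Wald on the coefficient scale, exponentiated.
* RNG: one numpy Generator per cohort consumed in a fixed field order, so
  identical (config, seed) reproduces tables bit-for-bit.

## Known limitations

The CACE-to-hazard-ratio conversion from the probit coefficient is an
approximation, accurate for rare per-period events. 2SRI standard errors
ignore first-stage uncertainty. The marginal MSM contrast is subject to
hazard-ratio noncollapsibility, so even a perfectly weighted fit is not
numerically identical to the conditional log hazard ratio; the recovery
study shows the discrepancy stays well within ±0.1 at the default event
rates. Under heavy crossover the time-invariant estimand diverges from
the pure treatment effect, as discussed above.
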