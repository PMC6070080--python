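# rdipw

Causal survival analysis around a treatment-eligibility threshold: fuzzy
**r**egression **d**iscontinuity and **i**nverse-**p**robability-**w**eighted
marginal structural models for discrete-time hazards, plus a synthetic-cohort
simulator with known ground truth.

## The problem

In many HIV treatment programmes, antiretroviral therapy (ART) was assigned
by a threshold rule: patients became eligible once their CD4 count dropped
below 200 cells/μL. Observational estimates of the effect of ART on
mortality from such programmes are confounded by indication — sicker
patients (lower CD4) are both more likely to start treatment and more likely
to die — so the naive treated-vs-untreated hazard ratio points the wrong
way. Two designs with very different identifying assumptions can recover the
causal effect:

* **Fuzzy regression discontinuity (RDD).** Patients presenting just below
  and just above the threshold are exchangeable if the potential outcomes
  are continuous at 200 cells/μL. The threshold shifts only the
  *probability* of initiating ART (a fuzzy design), so the eligibility
  effect is an intention-to-treat (ITT); instrumenting actual treatment
  with eligibility gives the complier average causal effect (CACE).
* **IPW marginal structural models (MSM).** Under no unmeasured confounding,
  weighting each subject by the inverse probability of the treatment they
  actually received creates a pseudopopulation in which treatment is
  independent of the measured confounders; a weighted discrete-time hazard
  model then estimates the marginal effect. Time-varying treatment and
  informative lab-gap censoring are handled by cumulative-product
  stabilized weights.

Both pipelines run on a **person-period table**: one row per subject per
month at risk, with the per-period death indicator modelled by a binomial
GLM. With a complementary log-log link,

```
cloglog P(T = t | T ≥ t, x) = α_t + β'x,
```

the coefficients β are discrete-time log hazard ratios, comparable across
period lengths.

The ITT model regresses the event indicator on eligibility, side-specific
CD4-gap slopes `(CD4 − 200)·1{below}` and `(CD4 − 200)·1{above}`, and smooth
period effects; `exp(β_eligible)` is the eligibility hazard ratio. The CACE
is estimated by maximum likelihood of the ivprobit system (linear first
stage for treatment with eligibility as the instrument, probit outcome,
correlated errors), with a two-stage residual-inclusion (2SRI) fallback.
Weight models are logistic; weighted fits use subject-clustered sandwich
variances.

Because no comparable public cohort exists, the package ships a simulator
(`rdipw.simulate`) that generates cohorts with this exact structure — CD4
on 0–350 cells/μL with density continuous at the threshold, a jump in
uptake at 200, a CD4-driven mortality gradient, a true conditional hazard
ratio of 0.5, 6-monthly lab visits with misses and disengagement, and a
32-asset PCA wealth index — so every estimator can be validated by
parameter recovery against known truth.

## Worked example

```python
from rdipw import (SimConfig, generate_cohort, expand_person_periods, RDDSpec,
                   BandwidthWindow, fit_itt, fit_cace, fit_first_stage,
                   fit_baseline_weights, fit_msm, fit_unadjusted_and_adjusted)

cfg = SimConfig(n_subjects=4435, seed=1)          # study-scale cohort, true HR 0.5
cohort, truth = generate_cohort(cfg)
pp = expand_person_periods(cohort)

fs = fit_first_stage(cohort, window=(150, 250))
itt = fit_itt(pp, RDDSpec(window=BandwidthWindow(0, 350)))
cace = fit_cace(pp, RDDSpec())
unadj, _ = fit_unadjusted_and_adjusted(pp)
msm = fit_msm(pp, fit_baseline_weights(cohort).row_weights(pp), "time-invariant")
```

Printing each fit's `hr_` and `ci95_` gives:

```
first-stage jump in 6-month ART uptake: 0.71 (0.63, 0.78)
RDD ITT  HR 0.72 (0.51, 1.03), 716 deaths among 4435 subjects
RDD CACE HR 0.52 (0.22, 1.11) [ivprobit-ml (probit-to-HR at covariate means)]
unadjusted HR 1.80 (1.53, 2.12)
IPW MSM  HR 0.76 (0.62, 0.94)
```

Reading the numbers: the threshold moves 6-month ART uptake by 71 points in
the 150–250 window, a strong first stage. The unadjusted hazard ratio of
1.80 says treated subjects die *more* — pure confounding by indication,
since the true conditional hazard ratio in this cohort is 0.50. The CACE
(0.52) undoes the ITT's dilution by non-compliance; the IPW MSM (0.76) is a
marginal contrast attenuated here by control-arm subjects who initiate ART
later in follow-up.

The same pipeline is available from the shell:

```sh
rdipw simulate --out-cohort cohort.csv --out-truth truth.csv --seed 1
rdipw prep --cohort cohort.csv --out pp.csv
rdipw rdd --pp pp.csv --cohort cohort.csv --out rdd.kv
rdipw msm --pp pp.csv --cohort cohort.csv --out msm.kv
rdipw report --cohort cohort.csv --pp pp.csv --out-dir report/
```

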