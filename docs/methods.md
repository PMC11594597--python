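# Methods

`bpround` quantifies how zero end-digit preference in systolic blood
pressure (SBP) recording — the routine habit of rounding a reading to the
nearest 10 mmHg — propagates through a Cox proportional-hazards 5-year
cardiovascular-disease (CVD) risk equation into risk-category
misclassification and, from there, into healthcare cost. The cohort it is
designed around (a New Zealand primary-care risk-assessment population) is
access-restricted, so the package ships a synthetic cohort generator that
reproduces the statistical structure the analysis depends on; every
downstream stage is exercised and tested against that generator.

## Risk model

Time to first CVD event follows a proportional-hazards model

    h(t | z) = h0(t) · exp(β′z),

with the covariate panel used by New Zealand primary-prevention equations:
centred age, centred SBP, centred TC:HDL ratio, ethnicity (European
reference), deprivation quintile (NZDep 1 reference), ex/current smoking,
family history of premature CVD, atrial fibrillation, diabetes, BMI class
(normal reference) and three baseline medication flags — 25 design columns.
Coefficients are estimated by maximum partial likelihood with Efron tie
handling (via `lifelines`; Newton precision tightened to 1e-9 so small flat
likelihoods are maximised to ≲1e-5). Absolute risk at five years is

    risk% = (1 − S0(5)^exp(β′z_c)) · 100,

where `z_c` is the covariate vector with continuous terms centred at the
fitting sample's means and S0(5) is the Breslow baseline survival
`exp(−H0(5))`, with `H0` the cumulative baseline hazard anchored at the
baseline subject: centred continuous covariates at zero, categoricals at
their reference level. (The library's own baseline is anchored at the mean
of *all* design columns, including indicator blocks, so the baseline is
computed in-package from the fitted coefficients.)

Numerical safeguards: a fit with no events raises a degenerate-fit error; a
coefficient beyond |log HR| > 20 or a curvature-based standard error above
50 raises a separation error (monotone likelihood). In the full design an
indicator level with no events among the exposed has a monotone likelihood
in that one coefficient; such levels are merged into the reference with a
logged warning rather than poisoning the fit — at the default cohort sizes
this occurs only for very rare levels (e.g. underweight BMI in small test
cohorts).

Risk categories follow the NZ CVD management guidelines: low < 5%,
moderate 5–15%, high > 15% 5-year risk. The interval is read as closed at
both ends (5.0% and 15.0% are moderate); the guideline text does not fix
the boundary convention, so one was chosen and is applied everywhere.

## Rounding operator

End-digits 1–4 round down, 6–9 round up, and a terminal 5 is rounded up
with probability 0.5 (configurable) using a dedicated, seeded RNG stream.
The operator is idempotent, moves a value by at most 5 mmHg, and fixes
values already ending in zero. A `delta_scale` hook attenuates the signed
displacement for sensitivity analyses (0 disables rounding entirely); for
scales strictly between 0 and 1 the output need not end in zero.

## Synthetic cohort generator

One record per person. Defaults (chosen once, as the study conditions):

* `n_people` 40,000, 56.4% male; age ~ Normal(51.29, 10.07) for men and
  Normal(55.85, 8.87) for women, clipped to [30, 80] years.
* Categorical covariates drawn independently with prevalences matching the
  emulated population's margins (e.g. diabetes 10.9%, atrial fibrillation
  1.4%, current smoking 15.0%); smoking states are mutually exclusive.
  Covariate correlation is deliberately absent — only marginal totals are
  public — so joint-distribution effects (e.g. deprivation–smoking
  clustering) are not represented.
* Latent SBP ~ Normal(130, 16) truncated to [70, 250] mmHg, quantised to
  the device calibration grid. The default grid is 1 mmHg, so unbiased
  recordings carry every terminal digit (10% zeros); a 2 mmHg grid (20%
  zeros, even digits only) is a supported alternative. A
  Bernoulli(`rounded_fraction` = 0.25) subset is re-recorded with the zero
  end-digit operator, giving an observed zero share of
  0.1·0.75 + 0.25 ≈ 32.5%, the prevalence regime the analysis targets. The
  1 mmHg default matters: terminal 5s are the experiment's only source of
  between-simulation randomness, and they cannot occur on an even grid.
* Survival: exponential baseline (Weibull shape exposed, default 1) with
  rate 0.008/person-year at the baseline subject, hazard driven by the
  *latent* SBP — rounding is purely a recording error. Default log-hazard
  ratios are plausible magnitudes for a 5-year CVD equation (age 0.075/yr,
  SBP 0.013/mmHg, diabetes 0.50, current smoking 0.55, …); they are **not**
  the unpublished national-equation coefficients. Censoring is the minimum
  of an exponential (rate 0.02/yr) and administrative censoring at 5 years.
  These settings give an event fraction near 7% and a low-risk-dominated
  5-year risk distribution (most people < 5%, few > 15%).
* 5% of records carry a prior-CVD flag; they are excluded from modelling.

All randomness flows from named `SeedSequence` substreams (covariates,
survival, rounding), so identical seeds give identical tables.

## Digit audit and the three-group decomposition

The observed zero end-digit share `p_obs` is decomposed into non-zero
digits, *true* zeros expected from unbiased recording (`p_true`, default
0.20, the even-grid expectation), and excess zeros attributed to rounding.
The default estimator is the literal excess `max(0, p_obs − p_true)`; the
mixture-consistent inversion `(p_obs − p_true)/(1 − p_true)` — which
accounts for rounded values that would have ended in zero anyway — is
available behind a flag but off by default, preserving the plain-subtraction
reading (0.32 − 0.20 = 0.12). Applied to the default generator (true
rounded fraction 0.25 on a 1 mmHg grid) the literal estimator returns
≈ 12.5%: the audit inherits whatever bias its `p_true` assumption carries,
which is a property of the estimator, not a defect of the generator.

## Misclassification experiment

Per sex, on the subset with no prior CVD and a non-zero SBP end-digit:

1. Fit Model 1 once; compute each person's 5-year risk and category.
2. For each simulation b = 1..B: round every SBP (fresh rounding
   substream), refit Model 2 (warm-started from Model 1's coefficients),
   recompute risk with Model 2's own centring and baseline, re-categorise,
   and cross-tabulate original vs rounded categories (3×3).
3. Average the matrices; attach percentile (2.5th/97.5th) confidence
   intervals across simulations; report per-row percentages and the
   undertreated (moderate→low) and overtreated (low→moderate,
   moderate→high) totals. A representative Model 2 (first simulation) is
   compared with Model 1 via per-covariate relative hazard-ratio
   differences and a two-sided paired t-test across covariates on the HR
   scale (log-HR pairing available); identical fits return a flagged
   degenerate non-result with p = 1 by convention.

Model 1 is fitted once — only the digit-5 coin flips vary between
simulations — and non-convergent refits are dropped and counted, not
imputed. Between-simulation variability is therefore conservative: it
reflects only the digit-5 randomisation, not sampling variability of the
cohort itself.

The convergence diagnostic reports the percent correctly classified
(trace/total) as a function of simulation count, with a
normal-approximation 95% CI of the mean, whose width shrinks as 1/√B.

The full design uses B = 10,000 simulations (the `SimulationConfig`
default). The pipeline's desk profile runs B = 200 at ~20,000 people per
sex, which resolves the structural properties (zero corner cells, row
conservation, √B shrinkage) while keeping a full run in minutes on one
core; the two profiles differ only in Monte-Carlo precision.

Whole-cohort generalization scales the subset totals by
`rounded-fraction estimate / (experiment's rounded fraction of the
cohort)`, rounding half away from zero; an explicit scaling factor may be
supplied, and a zero experimental rounding fraction is an error.

Stratified rounding of a cohort subsample (for generalization studies)
partitions the non-zero-digit records into strata — by default quintiles of
age and SBP crossed with sex and diabetes; the "key CVD factors" are
configurable — and rounds a without-replacement simple random sample of
`round(f·m)` records per stratum, preserving stratum proportions to within
one record.

## Cost model

The bundled schedule (versioned YAML, user-overridable) prices one
assessment as GP visit + nurse visit + lipid profile + blood glucose + ECG,
each with min/mid/max tiers (mid annual bundle NZD 235.96); categories
imply 2/3/5 assessments over five years (low/moderate/high). Medication
bundles: none for low risk; statin + antihypertensive for moderate
(mid NZD 0.30/day); plus an antithrombotic for high. Medication cost uses
365 × 5 days (no leap days; this convention reproduces the schedule's
printed 5-year totals exactly, e.g. 0.30 × 1825 = 547.50). Overtreatment
into moderate is costed as count × (moderate − low) 5-year total at the mid
tier, with a max-tier bound computed the same way; this reconstruction
reproduces the published headline figures (≈ NZD 1.57M mid, ≈ NZD 8.2M max
for 2008 overclassifications) and is documented as a reconstruction — the
original arithmetic is not shown anywhere. Undertreatment is *not* given a
point estimate: the avoidable inpatient cost is reported as a scenario band
(NZD 1,200–5,500 per patient, ward to ICU). No discounting, inflation
adjustment or QALYs.

## What passing tests do and do not show

The generator matches the fitted model's functional form exactly, so
parameter-recovery and baseline-survival checks validate the estimation
machinery, not the realism of any particular coefficient set. Misclassified
counts and costs produced on synthetic cohorts are demonstrations of the
mechanism at configurable prevalences; they are not estimates for any real
population. Real-data features the generator does not emulate: covariate
correlation, secular trends in assessment uptake, measurement errors other
than terminal-digit rounding (cuff size, white-coat effects, calibration
drift), and any dependence of rounding propensity on the patient or
provider.

## Problem sizes

Unit tests run on cohorts of 2,000–10,000 people with 3–50 simulations;
the structural acceptance checks use 40,000 people (≈ 20,000 per sex,
≈ 13,500 per sex after subsetting) with 200 simulations; digit-frequency
checks use 100,000 draws. These sizes were chosen so the full suite
completes in a few minutes while every assertion retains comfortable
Monte-Carlo margins.
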