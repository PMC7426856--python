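# Methods

This package rebuilds, applies and validates a recalibrated Charlson
Comorbidity Index (CCI) for all-cause inpatient mortality on
administrative claims, and ships a synthetic claims generator so the
whole workflow runs without access to restricted registry data.

## Comorbidity ascertainment

Diagnosis codes are ICD-10, normalized to uppercase dot-free form and
matched by *prefix* against a coding table mapping codes to the 17
classic Charlson categories. The bundled table follows the published
Quan et al. (2005) ICD-10 coding algorithm (289 prefixes); it is a
plain CSV (`category_id,icd10_prefix`) and can be swapped for another
dialect. Prefix matching (rather than exact or regex matching) is used
because claims codes vary in specificity.

Severity pairs — moderate/severe liver disease over mild liver
disease, diabetes with end-organ damage over uncomplicated diabetes,
metastatic solid tumor over any non-metastatic tumor — are resolved so
only the severer member counts. The hierarchy is **off** when
reporting prevalences (each category counted independently, matching
how such tables are usually published) and **on** by default when
scoring (the classic Charlson convention). Both behaviours are exposed.

The comorbidity ascertainment window around the index admission is
ambiguous in most claims sources ("diagnosed before discharge" can
reach records beyond the admission month). `assemble_cohort` exposes
`ascertainment_months` (default 0: claims rows in the index month
only) instead of hard-coding a convention.

## Cohort construction

Time is month-granular throughout, because that is the resolution of
the source data model. The index admission is a patient's first-ever
admission in the study window (2002-01 to 2013-12 by default);
follow-up runs from the index month to the death month (event) or the
window end (censored). Patients dying in their index month are
excluded and tallied, since their follow-up would be zero; censored
patients admitted in the final window month are excluded for the same
reason. A death recorded before the index admission is a data
integrity error, not an exclusion.

The 70/30 development/validation split is stratified by the death
indicator: rows are shuffled within each death stratum with a seeded
generator and cut at `round(0.7 × stratum size)`, so both partitions
preserve the death rate to within one patient per stratum and the
partition is reproducible bit for bit.

## Weight recalibration

All 17 comorbidity flags enter one Cox proportional-hazards model of
follow-up time to death, adjusted for age group, sex, region and the
11-level family-income variable (indicator contrasts against a fixed
first level). Age grouping is configurable: decade bands (default,
10 levels), empirical quartiles, or the three broad strata <60/60–79/≥80.
Ties are handled by Efron's method by default (month resolution makes
ties heavy); Breslow is selectable.

Each comorbidity's adjusted hazard ratio is divided by the smallest HR
among the categories, giving relative weights with minimum exactly 1;
integer severity weights are the relative weights rounded to the
nearest integer, half away from zero. Rounding (not truncation) is the
convention because it is the only rule consistent with the published
pairs such as 1.595 → 2 and 4.608 → 5. The derivation is invariant to
rescaling all HRs and monotone in the HR.

Numerical choices:

- The partial likelihood is maximized with L-BFGS (projected-gradient
  tolerance 1e-9). The analytic-Hessian Newton path fails with a
  singular Hessian when a very sparse flag is nearly unidentified; at
  the default AIDS prevalence of 0.03% this happens regularly at
  moderate n.
- A flag with zero deaths among the exposed (or unexposed) has a
  monotone partial likelihood — the practical form of separation in
  these data. `fit_cox` raises a separation error naming the flag, per
  its contract. `CoxWeightRecalibrator(on_separation="drop")`, used by
  the end-to-end pipeline, instead drops such flags with a warning and
  reports them; an optional `min_exposed_events` screen (the pipeline
  does not set it; the scaling tests use 5) removes flags too sparse
  to estimate stably. Dropped categories get no weight; the CLI
  pipeline scores them neutrally with weight 1 and records that in its
  run manifest.
- Constant design columns are dropped with a warning before fitting.
- Wald 95% CIs and p-values come from the inverse information at the
  maximum.

## Scoring and risk groups

A patient's index score is the sum of integer weights over flagged
(hierarchy-resolved) categories; the classic 1987 weight table ships
alongside the recalibrated one. Risk groups follow the ≤50th /
50–80th / 80–90th / >90th percentile scheme. Because integer scores
are heavily tied, exact percentile masses are impossible; the cut-off
for percentile p is the smallest observed score s with empirical
CDF(s) ≥ p/100, and boundaries are inclusive below (score ≤ cut-off →
lower group). With the published cut-offs (1/3/5 classic, 1/4/6
recalibrated) this reproduces the published score bands 0–1 / 2–3 /
4–5 / ≥6 and 0–1 / 2–4 / 5–6 / ≥7.

## Validation metrics

The c statistic is the ROC area of a risk prediction against the
binary death outcome (the rank probability that a decedent outranks a
survivor, ties counted half), not a survival concordance; its CI and
the two-sided test for the difference of two correlated c statistics
use the DeLong pairwise-placement covariance. Predictions come from
logistic risk models: model 1 is the score alone, model 2 adds age
group (quartiles by default here), sex, region and income group. In
model 1 the fitted probabilities are a monotone transform of the
score, so the c statistic is identical either way.

Continuous net reclassification improvement (cNRI) compares paired
predictions: the event component is the net percentage of decedents
whose predicted risk rises under the new model, the non-event
component the net percentage of survivors whose risk falls, and the
total is their sum (an exact identity). CIs are asymptotic normal per
component with the two components treated as independent; a
patient-level bootstrap (configurable B and seed) is available because
CI construction conventions differ across implementations.

Kaplan–Meier curves per risk group use the product-limit estimator
(via lifelines); censored patients leave the risk set after their
follow-up month.

## Synthetic cohort generator

The generator emulates the structure of Korean national
health-insurance sample claims: month-granular admissions uniform over
2002-01..2013-11 (the final month is excluded so censored follow-up is
always ≥1 month), demographics drawn from the published strata
frequencies (46.3% male, 43.9% metropolitan, the 11-group income
distribution, age strata 73.8% / 20.9% / 5.3% with uniform ages within
each band), and the 17 comorbidity flags sampled independently at the
published prevalences (an optional pairwise odds-multiplier knob
induces correlation for robustness checks). Every flagged category
emits 1–3 ICD-10 codes drawn from the bundled mapping's prefixes, plus
0–2 non-Charlson noise codes; because the bundled prefix lists are
mutually exclusive, profiles rebuilt from emitted codes equal the
planted flags exactly.

Death times are exponential with rate λ₀·exp(lp), where lp sums the
planted per-comorbidity log HRs (published adjusted HRs by default)
and demographic effects, drawn in continuous time and floored to
months — reproducing the tie structure of month-resolved data and
making same-month deaths possible so the exclusion filter is
exercised. λ₀ is calibrated by root-finding so the expected death
proportion over each patient's own follow-up horizon equals the target
(3.83% by default, the published overall mortality), then multiplied
by an optional scale knob used for scale-invariance checks; a
configuration whose per-month hazard would exceed 1 is rejected.

Demographic log-HRs are not published and were fixed once at
field-realistic values: 60–79 vs <60 HR 4, ≥80 HR 12 (age dominates
inpatient mortality), male 1.4, metropolitan 0.95, medical aid +0.35
on the log scale, −0.02 per income decile.

What the generator deliberately does **not** emulate: correlation of
comorbidity burden with age (flags are independent of demographics),
multiple admissions per patient, cause-specific death, or seasonality.
A consequence worth knowing: absolute c statistics on synthetic data
are far below published real-data values (≈0.55 vs ≈0.83–0.86 for the
univariate model), because in real cohorts comorbidity correlates with
age and age drives mortality. Green tests therefore establish the
correctness of the machinery and the direction of comparisons, not
real-data effect sizes.

## Known limitations

- Integer-weight recovery is intrinsically unstable at moderate sample
  sizes: several published relative weights (1.595, 2.354, 3.646,
  5.43) sit essentially on rounding boundaries, and all weights share
  the noisy minimum-HR denominator. At ~1,300 development deaths
  (n = 50,000) roughly 3–5 of 17 integer weights are expected to flip
  on a typical draw; even at ~11,000 deaths (n = 400,000) 2–3 flips
  are common. Hazard-ratio recovery itself is accurate and its Wald
  CIs are well calibrated (tested).
- The AIDS category (prevalence 0.03%) is not estimable at moderate n;
  the pipeline drops it with a warning when it has no events.
- The DeLong test and cNRI treat predictions as fixed; refitting
  uncertainty in the logistic models is not propagated.
- No proportional-hazards diagnostics, time-varying effects, frailty
  or interaction terms.
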