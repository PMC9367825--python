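# Methods

This note records the statistical model, the measurement conventions, the
synthetic-data design, and the numerical choices behind `carecascade`, in the
order the pipeline runs.

## Study design assumed

The pipeline evaluates a treatment-only (pre/post) incentive program: adults
with HIV enrolled at several clinics, a baseline lab visit at enrollment,
follow-up viral-load monitoring at 6 and 12 months (± 1 month), conditional
financial incentives for completed labs and achieved suppression, a baseline
psychosocial survey, and a one-year micro-costing exercise per clinic. There
is no comparison arm; the longitudinal model estimates change over time
within the cohort, not a causal incentive effect.

## Eligibility screening

Base criteria (confirmed diagnosis, local residence, no plans to move within
12 months, age ≥ 18, English, not institutionalized or in a concurrent
study) plus at least one criterion from:

- **Category A** — no viral-load test in the last 8 months; or two
  *consecutive* detectable results (≥ 200 copies/mL) at least 90 days apart;
  or ≥ 2 missed visits in the last 6 months. "Consecutive" means adjacent in
  date order with no intervening test.
- **Category B** — diagnosed 3–12 months before screening with no
  viral-load test since diagnosis; or at least one self-reported risk factor
  (unstable housing, ≥ 3 months unemployed, incarceration history, a
  behavioral-health condition within the last 12 months).

Every "N months" clause uses a uniform 30-day month (8 months = 240 days);
Category A takes precedence when both hold, consistent with A being the
primary enrollment stratum. Both conventions are uniform and testable rather
than calendar-aware; switching to calendar months would move classifications
only for events within a few days of a boundary.

## Cascade outcome measurement

- A month is 30 days; the "12-month (± 1 month)" forward window is
  [anchor, anchor + 390 days], endpoints inclusive; the 6-month window is
  [anchor, anchor + 210 days].
- **t0** engagement/retention look back over [anchor − 360, anchor − 1]; t0
  suppression uses the enrollment-day test. The enrollment-day test is
  excluded from engagement/retention at *every* timepoint: it is the
  incented baseline study visit, not evidence of routine care, and counting
  it would classify the whole cohort engaged at follow-up by construction.
- Suppression at a reporting date is decided by the most recent test within
  ± 30 days; strict `< 200` copies/mL.
- **Missing-data convention:** a participant with no test in a window is
  classified negative, so cohort proportions are out of everyone enrolled
  (an intention-to-treat denominator). This is the only convention that
  makes proportions of all enrolled well defined, but it deliberately
  conflates non-attendance with clinical failure — follow-up suppression
  proportions under it are attendance-bounded. `cascade_table` exposes a
  `complete_case` alternative that restricts each timepoint's denominator
  to participants with ≥ 1 in-window test; the package does not assert which
  convention any given published figure used.

## Incentive accounting

Money is `Decimal` to the cent; the audit identities (per-participant
USD 140 intervention cap, Σₖ at-least-k = total lab events, at-least-k
non-increasing in k) are exact, never floating-point-approximate. Survey
compensation (USD 50 baseline / USD 15 follow-up) is on the same ledger but
outside the intervention cap. Incentives earned but not yet handed over at
study close count as distributed; `IncentiveEvent.distributed` preserves the
distinction. A duplicate suppression trigger is a protocol violation and
raises an audit error rather than silently deduplicating.

## Survey scoring

Acceptability is the mean of four 0–4 Likert items with item 4
reverse-scored, complete cases only. AUDIT-C hazardous-use cutoffs: ≥ 4 for
men, ≥ 3 for women and gender-minority respondents. PHQ-9 uses the standard
0–27 range (each score carries range metadata, since summaries of this
instrument are sometimes printed against a 24-point ceiling). The CASE
adherence index is taken as a 3–16 total and accepted directly when
item-level data are unavailable. The stigma scale is a 1–5 item mean;
item polarity is treated as already harmonized upstream.

## Regression models

**Trend.** Pooled logistic regression of each binary outcome on time
t ∈ {0, 1, 2} as a continuous counter, with cluster-robust (by participant)
standard errors. The "longitudinal" structure is handled in the variance,
not the mean; GEE-exchangeable and variational random-intercept variants are
options (`method="gee"` / `"mixed"`). Predicted probabilities are average
marginal predictions at each time value. Under complete separation in time
the fit falls back to a light L2 penalty (α = 1e-4) and flags
`penalized=True` with no standard error rather than reporting a divergent
estimate. Coefficients from a pooled logit are population-averaged; a
random-intercept logit of the same data yields larger (subject-specific)
coefficients, so coefficients published under an unspecified longitudinal
model are not generally recoverable from marginal proportions — the
package's validation is therefore property-based (oracle agreement,
confidence-interval coverage, type-I error) rather than
coefficient-matching.

**Correlates.** One logistic fit per 12-month outcome on the benchmark set
(age, race, ethnicity, gender, relationship, employment, housing, insurance,
site, enrollment category, baseline outcome), references White / Female /
Site A / Category B; when a preferred reference level is absent from the
analysis subset the modal level is used instead. Add-one models append a
single sparser covariate to the benchmark controls, are fit on that
covariate's complete cases, and report only its coefficient. A factor level
within which the outcome is constant (complete separation — e.g. a site with
no suppressed participants at follow-up) is dropped from the fit and listed
in `dropped_levels`. A continuous add-one covariate that adds no rank to the
benchmark design raises a collinearity error. No multiple-testing adjustment
is applied.

## Cost-utility analysis

Constants (2019 USD): T = 382,954 lifetime treatment cost per infection;
W = 195,838.58 per QALY; annual transmission rate 0.061 per unsuppressed
person-year; 0.039 QALYs per person-year of suppression; 5.83 QALYs per
averted infection; conservative bar USD 100,000/QALY. Person-years of
suppression are proxied by the net count of participants who newly achieved
suppression over the one-year analysis period.

Numerical conventions, fixed because they reproduce the bundled worked
example to the printed cent:

- A, Q1, Q2 are rounded half-up to 2 decimals *before* entering downstream
  formulas (Q2 uses the rounded A; the ratio uses the rounded A and Q).
- The ratio R = (C − A·T)/(A·Q) is reported both signed and in magnitude;
  R < 0 means averted treatment costs exceed program cost (dominant /
  cost-saving). Cost-effectiveness is judged on the magnitude against W and
  against the conservative bar.
- Societal cost = client + staff + materials; payor = societal − client.
- The combined threshold C/(T + Q·W) is also reported, with Q defaulting to
  5.83 (the denominator then prices one averted infection plus its QALY
  stream); the separate C/T and C/W thresholds are the primary outputs.
- Regional cost indexing is an identity pass-through hook (no published
  method to implement).
- Evaluation costs are excluded from C by construction of the inputs.

In the bundled example, clinics B and C's printed component costs do not sum
to their printed totals; the example fixes the materials component as the
residual of the total, which keeps every total-derived figure (payor totals,
unit costs, ratios, thresholds) consistent. Contact counts, which the source
material does not print, are the values implied by total ÷ per-contact cost.

## Synthetic cohort generator

The generator emulates the realized study conditions of a four-clinic,
781-participant cohort, and is the test bed for every downstream stage:

- **Demographics** drawn independently per variable from configurable
  marginals (defaults: 89.2% Black/African American, 53.2% male, 89.7%
  insured, 13.5% unstable housing, ...). Enrollment category A share
  defaults to the realized 58% (the protocol's ≥ 80% quota is available via
  `enforce_category_quota`).
- **Lab visits**: homogeneous event process per participant per period with
  period-specific rates — `visit_rate_base` per year pre-enrollment
  (default 1.2/yr, giving ~70% baseline engagement via 1 − e^{−1.2}), and
  `visit_rate_base × incentive_visit_boost` post-enrollment (default boost
  2.2, giving ~93% 12-month engagement). An enrollment-day baseline test is
  always generated.
- **Viral loads**: per-participant Bernoulli suppression indicators at each
  timepoint (`p_suppressed_given_visit`, default (0.62, 0.52, 0.40));
  suppressed tests are written as 50 copies/mL and detectable as 10,000 —
  clearly on either side of the 200 threshold, which is the only feature
  the classifiers use. Each test's value is governed by the indicator of
  the nearest timepoint.
- **Missingness** arises structurally (no test in a window), not by
  imputation flags, matching an observed-labs design; survey items are
  missing completely at random at a configurable rate (default 12%).
- **Reproducibility**: one master seed; per-participant child streams via
  `SeedSequence.spawn`, so participant i's data are invariant to cohort
  size.

What the generator does **not** emulate: within-person viral-load kinetics
or ART pharmacology, correlation between demographics and outcomes (all
draws are independent unless a test plants an effect), calendar effects
(e.g. pandemic-era visit disruption), or clustering of visit behavior by
site. Passing tests on synthetic cohorts therefore validate the *machinery*
(classification rules, ledger identities, estimator calibration), not any
substantive claim about real programs; follow-up suppression marginals in
particular are products of attendance and conditional suppression, so they
sit well below the conditional probabilities supplied.

## Problem sizes used in the checks

The test suite validates estimator behavior at the scales the methods are
meant for: oracle-equivalence of logistic fits on datasets up to 50 rows
(agreement to 1e-6 with an independent Newton–Raphson maximizer),
confidence-interval coverage and type-I error over 200 simulated replicates
of 150-participant × 3-timepoint panels (3-sigma binomial acceptance bands
around 0.95 and 0.05), and generator calibration on 781-participant cohorts
(3-sigma binomial bands per marginal). The full pipeline is exercised
end-to-end on cohorts of 40–200 participants.

## Known limitations

- Eligibility monotonicity holds for risk factors, but the Category A
  "no recent lab" clause is non-monotone in care contact by design: adding
  a recent suppressed test can remove eligibility.
- The trend model treats time linearly on the logit scale; with three
  timepoints a saturated (categorical-time) model would fit the margins
  exactly but is not what the pipeline reports.
- The add-one collinearity guard applies to continuous extras only;
  categorical extras rely on the fitting routine's own rank handling.
- Cost inputs are accepted as totals per component; the generator's sampled
  cost profiles are lognormal around per-client means and are intended for
  smoke testing, not for calibrated budget simulation.
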