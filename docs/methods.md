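# Methods

## The estimand and the estimator

The package estimates the adjusted incremental cost Δc and incremental QALY
Δe of an intervention assigned deterministically by a baseline score cutoff,
over a 6-month horizon, together with the decision quantities derived from
them (ICER or dominance verdict, cost-effectiveness-plane cloud, CEAC).

QALYs are the trapezoid between the two utility assessments,
`QALY = ½·(u₀ + u₆)·h` with `h = 0.5` years; neither costs nor QALYs are
discounted over the half-year horizon.  A QALY difference is also expressed
as equivalent days of perfect health using 365.25 days per year, rounded to
two decimals (the 365-day convention gives the same two-decimal figure for
differences of this magnitude).

The core estimator is a two-equation SUR system — 6-month total cost and
QALY each regressed on the treated indicator and the same adjusters:
baseline age, sex, ethnicity, living arrangement, education, comorbidity
count, baseline total cost and baseline utility.  The baseline score itself
is deliberately *not* an adjuster: it is collinear with assignment by
design, so adjustment leans on the baseline outcome measures instead.
Estimation is one-step feasible GLS; with identical regressors in the two
equations the GLS solution coincides exactly with per-equation OLS, which
the test suite exploits as an independent oracle.  The residual 2×2
covariance is still estimated and reported because the cost–QALY error
correlation is part of the output.  Categorical adjusters are
reference-coded with the reference level fixed as the alphabetically first
observed level, so designs are deterministic.

Uncertainty: nonparametric bootstrap, stratified by arm so every resample
preserves the design's arm imbalance (~85/15), with the m completed
datasets refitted per resample and the m treated-coefficient pairs averaged
into one replicate (bootstrap outer, imputation inner).  The alternative —
one random imputation per replicate — is noisier per replicate and was not
taken; averaging keeps B×m fits tractable and yields valid percentile
intervals under MAR.  Point estimates are the mean over m of the full-data
SUR fits (asserted equal to the average of per-dataset fits), and intervals
are 2.5/97.5 bootstrap percentiles, matching the simple percentile
reporting convention.  Inside the bootstrap the refits use an SVD
least-squares solve, so a resample in which a rare dummy column (e.g. a
99%-prevalent ethnicity level) becomes constant degrades gracefully instead
of failing; the treated coefficient is unaffected by the degenerate column.

ICER/dominance is a total function of (Δc, Δe): strictly more costly and
less effective is dominated, strictly cheaper and more effective is
dominant, Δe = 0 leaves the ratio undefined (labelled with the sign of Δc),
and anything else reports Δc/Δe with its quadrant.  The CEAC is
`P(λΔe − Δc > 0)` over a λ grid of 0–50 000 in steps of 1 000 GBP/QALY,
covering the conventional 20–30k decision thresholds.

## Costing

Costs are `count × unit cost`, with unit costs inflated to the reference
price year by an index ratio.  The NHS+PSS perspective covers community
care, hospital care, NHS mental-health services, depression medications and
social care; the societal perspective adds travel, productivity losses
(valued at median weekly earnings over a 37.5-hour week), charity support
(proxied at a paid home-care worker's hourly rate, since the services are
predominantly domestic), private mental healthcare and self-care.
Societal-only components are always computed and recorded but enter the
headline total only under the societal perspective, so
`total_societal ≥ total_nhs_pss` holds row-wise.

Medication cost is `daily dose × days taken × price per dose-unit-day`.  A
missing dose falls back to the formulary-recommended daily dose for the
drug; missing days fall back to the mean of the observed days for that drug
across the whole dataset, computed before any substitution; a drug with no
observed days at all is an error rather than a guess.  The multiplication
convention (price per mg-day rather than per pack) is a schema choice and is
documented in the unit-cost table; only the fallback rules are
substantive.

Extreme costs are retained untrimmed — multi-week in-patient stays occur in
the real world, and they are the main driver of sampling uncertainty in Δc
at realistic cohort sizes (see Limitations).

Baseline resource use is costed identically but serves only as an
adjustment covariate; it is never added into the 6-month totals.

## Missing data

Diagnostics are logistic regressions of missing-indicators (total cost
missing, QALY missing) on baseline covariates; perfect separation raises
rather than silently dropping terms.  Baseline covariates are completed by
mean (continuous) / mode (categorical) imputation, mode ties breaking
toward the lowest category in sort order.

Costs are imputed at the aggregated group level (community / hospital /
mental-health / medication / social / societal-other) rather than per visit
type: block missingness (an unreturned questionnaire section) leaves whole
groups missing together, and group-level imputation keeps the chained
models stable.  Utilities at both time points and the cost groups are then
multiply imputed by chained equations within each arm.  Each conditional
model is a linear regression of the incomplete variable on the baseline
predictors (age, sex, ethnicity, living arrangement, education, score,
comorbidities, baseline utility) plus the other incomplete variables at
their current fill; each missing cell receives the observed value of one of
the knn = 5 donors closest in predicted mean, drawn uniformly, with
distance ties broken toward the lowest row position before the draw.  PMM
guarantees every imputed value is an observed donor value, which preserves
zeros and skewness in the cost columns.  Chains run a fixed 10 cycles from
a random-observed-draw start; m = 40 independent chains by default
(following the rule of thumb that m should be at least the worst-case
percentage of missing data, exposed as a checkable helper).  A chain whose
imputed-cell means are still moving by more than half an observed standard
deviation after the last cycle sets a non-convergence flag and logs a
warning.

MNAR sensitivity uses pattern-mixture scaling of *imputed cells only*:
utilities ×0.9 and/or costs ×1.1, per arm, in the seven standard
combinations (both-arm utility, both-arm cost, both, and each single-arm
variant).  The 10% shift is interpreted multiplicatively — "10% worse" read
as a proportional change to the imputed value; an absolute shift of 10% of
the mean is the main alternative reading and is not implemented.  A scaled
utility falling outside [−0.594, 1] is clamped back to the index range and
the clamp is logged (relevant only for negative imputed utilities, where a
×0.9 multiplier would otherwise *raise* the value out of range).

## The synthetic cohort

The generator emulates the study conditions every downstream stage assumes:

* n = 1020 participants aged ≥ 65; assignment score 0–15 drawn from a
  truncated-geometric distribution with ratio 0.688, putting ~15.4% of mass
  at or above the cutoff of 5 (an ~863/157 arm split in expectation);
* baseline utility `0.93 − 0.028·score + N(0, 0.12)`, clipped to
  [−0.594, 1]; 6-month utility = baseline + drift (−0.01) + treatment
  effect + N(0, 0.10);
* the default treatment effect on 6-month utility is −0.024, i.e. a true
  adjusted incremental QALY of −0.006 over the half-year; the cost effect
  is Poisson(0.925) extra primary-care contacts in the treated arm, i.e.
  ~£37 at the default £40 contact cost.  These configured truths give the
  recovery and coverage tests a known target.  A raw positive utility
  change with a negative adjusted QALY difference cannot coexist in a
  correctly specified linear generator, so the positive-change variant
  (+0.03) is exercised separately by the confounding/sign-reversal test;
* resource-use counts are two-part per category: Bernoulli(any use),
  logistic in the score at baseline, times `max(1, round(lognormal))`.
  Six-month any-use depends on the score only through baseline use (a
  +2.0 logit bump for baseline users) — and, for the 6-month-only
  mental-health category, through baseline utility — so the confounding
  runs through the measures the analysis adjusts for and the configured
  effects are identifiable.  Real data need not satisfy this; passing
  recovery tests therefore show the estimator works under its own
  assumptions, not that regression adjustment suffices for any
  cutoff-allocated cohort (that doubt is exactly what the score-band
  subgroup analyses probe);
* among 6-month in-patient users, 2% have an extended ~38-night stay
  (~£21.7k at the default per-night cost) — about one per cohort draw;
* missingness is blockwise (whole questionnaire sections at once) with
  logistic MAR rules: ~35% missing 6-month utility and ~30% missing
  6-month costs, women and higher scorers more likely missing; small rates
  on baseline blocks; an optional MNAR term adds the participant's own
  to-be-hidden value to the logit;
* antidepressant records carry typical doses and 14–182 day durations,
  with 10% of doses and days missing to exercise the fallback rules.

The generator does **not** emulate: real EQ-5D response profiles (utilities
are drawn directly on the index scale; a synthetic mapping table exists
only to test the lookup machinery — published value sets are licensed and
must be user-supplied), per-visit-type cost structure below the group
level, longitudinal score trajectories, or recruitment behaviour.  The
joint distribution of costs and utilities is plausible rather than
calibrated to any real dataset.

## Numerical choices and degenerate inputs

* Seeds: every stochastic stage (cohort, missingness, each imputation
  chain, bootstrap) derives from an explicit integer seed via
  `SeedSequence` spawning; identical config + seed reproduces byte-identical
  outputs.
* SUR: rank-deficient point-estimate designs and single-arm data raise;
  a residual covariance with condition number above 1e12 raises as
  singular.
* Balance tests: Welch (unequal-variance) t-test for continuous
  covariates, chi-squared on the arm×category table for categorical ones,
  without continuity correction by default (configurable for 2×2);
  covariates constant across both arms are skipped with a flag, and no
  multiplicity adjustment is applied (the table is descriptive).
* Score bands must contain scores on both sides of the cutoff; a band
  leaving an arm with fewer than two participants raises.
* Utility mapping is an exact lookup; an unknown (levels, age band, sex)
  key raises naming the combination — no silent default utility.

## Problem sizes

The acceptance script runs the full study-scale configuration: n = 1020,
m = 40, B = 1000, all four analysis families (~2 minutes on one CPU).  The
test suite scales Monte-Carlo checks to the smallest sizes that still
discriminate: recovery at n = 5000, coverage over 200 repeats at B = 200,
cohort-moment checks at n = 10 000–40 000, pipeline round-trips at
n = 200–400 with m = 2–5 and B = 20–100.

## Known limitations

* With heavy-tailed hospital costs retained untrimmed, the sampling
  distribution of Δc at n ≈ 1000 is wide and mildly heavy-tailed: single
  cohort draws scatter by tens of pounds around the configured truth, and
  rare extended stays induce a small residual confounding bias that
  baseline total cost does not fully absorb.  The acceptance script
  therefore reports percentile intervals alongside the point estimates.
* The pipeline's adjustment is linear; clipping utilities at the index
  ceiling attenuates effects for cohorts concentrated near full health.
* MNAR scenarios scale imputed cells only and are multiplicative; they are
  a sensitivity device, not a general delta-adjustment framework.
* Multilevel (practice-clustered) imputation and two-part/GLM cost models
  are out of scope.
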