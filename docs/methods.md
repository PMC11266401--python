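# Methods

This note documents the statistical model behind `kmsacost`, what the
synthetic claims generator does and does not emulate, the numerical and
design choices that were genuinely open, and the limitations a user should
know before trusting output on real data.

## Study design emulated

A retrospective matched-cohort cost-of-illness design on administrative
claims. Newly diagnosed cases of AL amyloidosis are identified from ICD-10
codes E85.4/E85.8/E85.9 (configurable) between 2016-01-01 and 2018-12-31;
the index date is the first claim bearing a qualifying code. A patient
qualifies with at least one inpatient claim or at least two outpatient
claims (any diagnosis position) carrying a qualifying code, the outpatient
pair at least 30 days apart — evaluated as last-minus-first qualifying
outpatient date ≥ 30 d, which is equivalent to the existence of one such
pair — plus any biopsy procedure claim within the closed window
[index − 365 d, index + 182 d]. Exclusions, in fixed first-match-wins
order: any 2015 claim with legacy ICD-9 code 277.3; a confirmed non-AL
record in a catastrophic-illness-style registry (ICD-9 277.3 / ICD-10
E85.1); a post-index switch to another amyloidosis code (E85.0, E85.1,
E85.2, E83.3 — the last implemented as printed in the source criteria; it
is plausibly a typo for E85.3 and is configurable).

Comparators with no amyloidosis-coded claim anywhere in the data window are
matched 1:10 exactly on sex, residential region (six NHI regions), and age
in completed years at the case's index date, drawn uniformly without
replacement in ascending case index-date order; each comparator serves at
most one case. Exact-year age matching is the strictest reading of "matched
on age" and is what the generator guarantees feasible by cloning matching
keys onto pool members. An optional ±1-year age fallback exists but is off
by default.

## The KMSA estimator

Follow-up [0, 1095) days is partitioned into seven modelling periods:
quarters of 91/91/91/92 d in year 1, half-years of 183/182 d in year 2, and
year 3 whole. (Mortality in the emulated population is stable after the
first year, which is why quarters are collapsed; a 12-quarter scheme is
available via `QUARTERLY_SCHEME` for sensitivity analyses.) Each patient ×
period cell gets a status: `complete`, `died_within` (death inside the
period and observed), `censored_within` (data end inside the period while
alive), or `not_entered`. Cells with `died_within` keep their partial
accrual and are treated as complete for model fitting — death terminates
cost accrual legitimately; `censored_within` cells retain observed costs in
the panel but are excluded from fits; no within-period interpolation is
done.

Per cohort, component and period, the conditional mean is a two-part model:
logistic regression for P(Y > 0) and a log-link GLM on the positive part —
gamma for costs, negative binomial (fixed dispersion alpha = 1, both
configurable) for counts. Covariates: age in years (continuous by default;
decade-band indicators available), sex, five region contrasts, and six
comorbidity indicators ascertained over the baseline year
[index − 365, index − 1] with the two-outpatient-or-one-inpatient rule
(prefix code matching, no date-gap requirement, same-day outpatient claims
count separately). Recycled predictions average the fitted
P(use|x)·E[Y|use,x] over the cohort's *own full* baseline membership,
making each cohort's estimate self-contained and the case-minus-comparator
subtraction interpretable.

The cumulative estimate at horizon h sums S(s_p)·mu_p over periods starting
before h, where S is the cohort's Kaplan–Meier survival function (deaths
before censorings at ties, S(t) = P(T > t) evaluated at period starts, so
the first period always has weight 1). This identity is exact in
expectation: E[cost in p] = P(alive at s_p) · E[cost in p | alive at s_p],
with the death-truncated accrual inside the conditional mean.

Degenerate fits are handled without crashing: an all-zero cell is a
structural zero (mu_p = 0); an all-positive cell records P(use) = 1; a
separated logistic fit (any non-intercept coefficient beyond 15 in absolute
value, or a statsmodels failure) falls back to intercept-only with a logged
warning, as does a positive part with fewer positive observations than
coefficients plus one. With intercept-only parts the two-part mean reduces
exactly to the cell's sample mean, which is what makes the
no-censoring/no-death equivalence with the crude mean hold to machine
precision.

Inference is a nonparametric bootstrap: patients resampled with replacement
within each cohort at the original size (the literal reading of "samples of
equal size with replacement"; matched sets are broken by default, and a
set-preserving mode is provided for sensitivity). Every replicate refits
the KM weights and all two-part models — the statistically coherent
refit-per-replicate reading — and percentile 2.5/97.5 intervals are
reported (a normal-approximation interval can be formed from the reported
SD). The p-values attached to cohort contrasts are two-sample pooled
t-tests on per-patient observed 3-year totals, mirroring the table-footnote
convention of the emulated study, not bootstrap tests.

## Synthetic claims generator

The generator is the package's stand-in for a non-public national claims
database. It emulates, with defaults calibrated to the published cohort:

- **Demographics.** Sex (59.07% male), six regions at the published mix,
  age drawn uniformly within published decade bands; the open-ended top
  band is [80, 91) so the mixture mean is 60.81 y against the published
  60.78 y. Index dates uniform on 2016-01-01..2018-12-31; administrative
  data end 2019-12-31.
- **Mortality.** Piecewise-exponential with breakpoints at 90/182/1095 d,
  hazards solved analytically so cumulative mortality passes exactly
  through 8.4% / 12.1% / 18.8% (cases) and 0.9% / 3.7% (comparators). Death
  days are the ceiling of the continuous draw (never day 0). Survival is
  independent of the censoring mechanism and of covariates.
- **Comorbidity.** Six independent Bernoulli indicators per person at the
  published cohort-specific prevalences (no printed joint distribution
  exists, so correlation between categories is deliberately not modelled).
  Positive categories are *planted into claims* by tagging two baseline
  outpatient claims (or one inpatient, appending visits only when the
  baseline has too few), so the flagging module recovers exactly the
  planted indicators.
- **Utilisation and cost.** Per period and setting, a hurdle process:
  any-use Bernoulli (logit-linear in centred age, sex and comorbidities),
  a shifted negative-binomial count given use, binomial thinning by the
  fraction of the period alive, and i.i.d. gamma per-claim costs whose mean
  is log-linear in the same covariates. Medication/non-medication is a
  fixed per-setting split. Calibration is analytic: intercepts are solved
  on an exact enumeration of the discrete covariate profiles (age by
  quadrature) so that *crude annual means over entering patients* — the
  quantities the study's figures print, death attrition included via the
  survival integral — equal the targets: year-1 case means of 37.88
  outpatient visits, 0.97 ER visits, 1.15 admissions, 12.02 hospital days,
  NT$ 294,490 total (179,740 outpatient / 108,450 inpatient / 6,300 ER;
  121,250 medication). Comparator intensities are not printed in the source
  and are back-solved from printed ratios (103% more outpatient visits,
  177% more ER visits, 4× admissions, 5.5× hospital days, >6× total cost,
  stationary across years and calendar time). Case year-2/3 totals use the
  printed NT$ 175,400 and 152,180 with setting splits chosen to respect the
  printed year-over-year changes (−56% admissions and −38% hospital days in
  year 2; ER visits and admissions ticking up in year 3); pre-index-year
  intensities are elevated but below year-1 levels. These unprinted values
  are package choices, fixed once.
- **Case and trap patterns.** Qualifying diagnosis patterns are planted by
  *relocating and tagging claims already drawn from the cost process*
  (earliest year-1 outpatient visit moved to day 0 and AL-tagged; first
  admission, or a ≥ day-30 outpatient visit, tagged to complete the rule),
  so cost calibration is untouched; a biopsy procedure code is attached to
  an existing baseline visit. Configurable fractions of "trap" persons get
  patterns the cohort builder must reject: a single outpatient AL claim;
  two AL claims under 30 days apart; a qualifying pattern without biopsy;
  a 2015 ICD-9 277.3 claim; a post-index switch code; a non-AL registry
  flag. Trap claims are appended (traps never enter an analysis cohort, so
  their costs are immaterial).
- **Anchoring.** Cases and traps are simulated on the index-anchored period
  grid including the pre-index year; comparator-pool members are simulated
  as a calendar-stationary process over 2015-01-01..data-end, so any
  assigned reference date sees the right expected intensity. In
  `run_study`, comparator outcomes and claims are generated *after*
  matching, relative to the assigned reference date, which keeps baseline
  comorbidity planting and mortality exactly aligned with the analysis
  windows; a standalone `simulate` anchors pool members to their latent
  (cloned) reference date, where a downstream matcher that reassigns a
  comparator to a different case can slightly attenuate measured
  comparator comorbidity prevalence.

A claim-free fast path (`simulate_period_totals`) draws patient × period
totals directly — a sum of i.i.d. gamma claim costs is a single gamma with
summed shape — and is distributionally identical to aggregating the claim
table up to per-claim integer rounding and the truncation of inpatient
stays at death. It exists for experiments that need hundreds of replicate
datasets (bootstrap calibration); the claim-level path is the reference and
the two are cross-checked in the test suite.

Everything is a pure function of (config, seed); stage-level generators are
derived deterministically from the seed and a stage label, and `run_study`
spawns per-stage integer seeds from its single top-level seed.

### What the generator does not emulate

Real fee-schedule code granularity and reimbursement adjudication;
dependent censoring or loss to follow-up (coverage is universal by
assumption); covariate-dependent mortality; correlated comorbidities;
within-person serial correlation of costs beyond what the shared covariate
multipliers induce; seasonal or calendar trends in case intensity; ICD-9
coding of pre-2016 baseline claims (all generic diagnoses are ICD-10
regardless of service year). Passing tests therefore demonstrate that the
estimation machinery is correct under the stated data-generating
assumptions, not that those assumptions hold in any particular real
database.

## Parameter defaults that matter

| Parameter | Default | Units / meaning |
| --- | --- | --- |
| `n_cases` | 645 | cohort size of the emulated study |
| `comparator_pool_size` | 30 × n_cases | 0 allowed for case-only runs; ≥10× required otherwise |
| matching ratio | 10 | comparators per case, without replacement |
| period scheme | 91/91/91/92/183/182/365 d | collapse of 12 quarters |
| biopsy window | (−365, +182) d | closed interval around index |
| part-2 family | gamma (costs), NB α=1 (counts) | log link |
| bootstrap B | 1000 (`run_study`), 200 (acceptance script) | percentile CI |
| trap rate | 0.01 per type | fraction of n_cases |

The acceptance script uses B = 200: the reported SDs and intervals
stabilise well below the study's B = 1000, and the full setting is one flag
away.

The pool multiplier of 30 deserves a note: with exact-key matching,
uniform draws and no replacement, a case's cloned twins can be consumed by
an earlier case whose eligibility set overlaps asymmetrically (same
completed age at one index date but not the other). Thirty clones per case
makes pool exhaustion practically impossible at the design sizes used
while keeping the matching algorithm exactly the specified uniform draw.

## Numerical choices

- KM ties: deaths processed before censorings; S evaluated exclusively
  (P(T > t)); evaluation beyond the last observed time carries the last
  value forward with a logged warning.
- Completed age uses calendar arithmetic (year difference minus one before
  the birthday), not day counts divided by 365.25; the regression age is
  the continuous days/365.25 value.
- Integer NT$ everywhere in claims; the medication split rounds the
  medication part and assigns the remainder to non-medication, so the
  per-claim identity medication + non-medication = total is exact.
- Percentages in reports round half away from zero to whole percent.
- Logistic separation guard at |coefficient| > 15; GLM fits use IRLS with
  tolerance 1e-10 and fall back to closed-form intercept-only means on any
  failure (logged).
- Generator death days beyond 20,000 d are recorded as no death (they are
  indistinguishable beyond the data end and would overflow date types).

## Known limitations

- Setting-level KMSA components are modelled separately from the total and
  do not sum to it exactly — intentional, and mirrored by the emulated
  study's own tables; only the within-panel-row additivity is an invariant.
- The crude annual summary's denominator (patients entering the year) is
  one of two defensible conventions; `denominator="all"` gives the other.
- Bootstrap p-values are not computed; the reported p-values are t-tests
  on observed totals and are anticonservative for heavily skewed costs at
  small n.
- With rare covariates (e.g. a 0.1%-prevalence comorbidity in a small
  comparator cohort) the logistic part falls back to intercept-only for
  that cell; estimates remain valid but lose covariate adjustment there.
- The generator's medication share is constant within cohort and setting
  across years; year-specific medication splits beyond year 1 are not
  printed in the source material and were not invented.
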