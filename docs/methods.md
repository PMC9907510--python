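# Methods notes

## Dispensing model

Antibiotic dispensing per child is modelled as a piecewise-constant Poisson
process on age `a ∈ [0, 1825)` days with intensity `r(a)·λᵢ·Mᵢ/Z`:

- `r(a)` — the age-band rate schedule, in courses per child per 365-day year.
  Defaults: 0.60 on days 0–180, 1.9 on days 180–730, 1.2 on days 730–1825.
  All durations use a 365-day year consistently, so the implied 5-year mean
  is `0.60·180/365 + 1.9·550/365 + 1.2·1095/365 = 6.7589` courses/child.
- `λᵢ ~ Gamma(shape k, mean 1)` — the child's frailty. The mean is pinned at 1
  (scale = 1/k) so `k` is a pure dispersion knob, identifiable separately
  from the rate schedule.
- `Mᵢ` — product of the rate multipliers of the child's chronic conditions;
  condition indicators are drawn independently across the 19 body systems at
  their configured prevalences (only marginal prevalences are available to
  calibrate against, so no dependence structure is imposed).
- `Z = E[λ]·E[M] = Πⱼ(1−pⱼ+pⱼmⱼ)` — computed analytically from the config,
  not from the realized sample, so the marginal band rates stay exactly
  `r(a)` and all expected values remain closed-form for test oracles.

Marginalising λ gives, per condition profile, a negative-binomial count with
size `k`; marginalising conditions gives a finite NB mixture. `pedabx.mixture`
evaluates its pmf by the standard two-term recursion, the zero class in
closed form, and the top-`q` share by descending tail sums with fractional
allocation of the boundary count.

## Calibration

Dispersion is not directly observable from published rate schedules, so the
default configuration solves two equations in two unknowns on the analytic
mixture: the zero-class probability equals 0.09 (91% ever-dispensed by age 5)
and the top-20% share of courses equals 0.52, with the pulmonary/respiratory
prevalence fixed at 0.183 and its multiplier free. The solution —
`k = 1.43454`, pulmonary multiplier `m = 2.04800` — is frozen in
`pedabx.config` and reproduced by `calibrate_default_config` (residuals
< 1e−6; the calibration never uses simulation).

The share-versus-multiplier curve is U-shaped around `m = 1` (both protective
and aggravating multipliers add population heterogeneity), so a share target
can admit two roots at the same zero-class target; the solver returns the
root closest to `m = 1` (the most parsimonious departure from the null).
Targets below the attainable frontier raise an error reporting the frontier.

## Claims emission

Each ground-truth course event optionally emits an outpatient visit on the
event day and always emits a pharmacy fill at `event day + lag`, with the
lag drawn from a distribution supported on 0–7 days (default pmf 0.50, 0.20,
0.10, 0.07, 0.05, 0.04, 0.02, 0.02; mean 1.27 d — most fills are dispensed
the day of or the day after the visit). Respiratory events carry a
respiratory ICD code in diagnosis field 1 or 2 (position random); all other
emitted fields hold acute non-respiratory codes that match no chronic-code
prefix. Decoy visits (no associated fill, default 2.0/child/year) and
non-antibiotic fills (default 0.5/child/year) exercise the linkage window
and the drug-class filter. Each chronic condition a child holds emits two
outpatient visits carrying a matching PMCA-prefix code, making the condition
recoverable from claims alone. Claims before 2015 are coded ICD-9, later
ones ICD-10, exercising the version-keyed crosswalk.

Under these defaults the *recovered* respiratory share is slightly below the
generated 71%: a course is misattributed when some non-respiratory visit
(decoy, chronic, or another event's visit) falls inside its lookback window
more recently than its own visit. With the default lag and visit rates the
expected flip rate is ≈0.5–1%, i.e. a recovered respiratory fraction of
≈70.4% — the attribution machinery is exact, the residual is an inherent
ambiguity of lookback linkage. The pure decoy mechanism is verified against
its closed form `1 − exp(−d·L/365)` in the tests with a degenerate lag.

One consequence of the `event + lag` construction: a fill can trail the
horizon by up to 7 days, and such fills (≈0.06% of courses) are excluded at
course construction, so measured 5-year means sit ~0.004 courses below the
analytic 6.759. Likewise same-day same-class collisions collapse at dedup
(~0.06%). Both effects are far inside the Monte-Carlo noise at the cohort
sizes used.

## Analysis conventions

- **Courses.** One course per fill after exact same-day same-class dedup; a
  `course_collapse_days` knob exists for sensitivity analyses but defaults
  to 0.
- **Linkage window.** Inclusive at both ends, `[fill − 7 d, fill]`; same-day
  visits qualify; ties on the most recent day resolve deterministically to
  the smallest claim id. The vectorised implementation (searchsorted on
  child×day keys) is property-tested against a per-fill brute-force scan.
- **Respiratory attribution** uses diagnosis fields 1–2 only, regardless of
  ICD era; unmappable codes count as non-respiratory and are tallied in the
  log. Unlinked courses are attributed "other" and remain in all totals.
- **PMCA tagging** uses *all* diagnosis fields (the 2-field restriction is an
  attribution rule, not a chronic-condition rule), longest-prefix match
  after dot-stripping and uppercasing, on outpatient claims only (a design
  choice; inpatient claims are out of scope here).
- **Enrollment continuity** is day-granular with zero gap tolerance by
  default (`max_gap_days` knob for sensitivity runs); overlapping spans
  merge silently.
- **Weights** are `census/sample` per state × sex stratum (optionally ×
  birth year, splitting age-aggregate census counts evenly across years).
  All headline estimates default to weighted, with an unweighted switch;
  because the default generator samples states and sexes proportionally to
  its census table, weighted and unweighted estimates coincide up to noise,
  which is itself a tested invariant.
- **Curve CIs** are normal-approximation bands for a weighted mean
  (`se² = Σwᵢ²(xᵢ−x̄)²/(Σw)²`), matching a two-tailed t test at these n;
  **band rates** instead carry exact (Garwood) Poisson intervals from
  chi-square quantiles, computed on the unweighted count and scaled to the
  weighted rate. The two conventions intentionally differ and are both
  reported.
- **Top-q share** uses fractional allocation of the boundary child's weight,
  making the share independent of tie order; the regression's binary label
  instead uses a whole-child rule (label = count strictly above the smallest
  threshold whose upper tail is ≤ q), so the labelled fraction never
  exceeds q and ties never straddle the boundary. These are two deliberate
  resolutions of the same discreteness ambiguity.
- **Regression.** Bernoulli-logit likelihood fitted by IRLS to gradient norm
  < 1e−8 (the additive error sometimes written on the log-odds scale is not
  separately identifiable, so the standard Bernoulli reading is used).
  Separation is detected as any |β| crossing 15 during iteration and raises
  naming the covariate; constant indicators are dropped with a warning.
  Inference is Wald (OR, CI, two-sided p), unweighted, all indicators
  entered jointly.

## What the generator does and does not emulate

Emulated: overdispersed per-child course counts with the observed zero class
and concentration; age-dependent dispensing; respiratory vs other mix;
chronic-condition prevalences with an elevated pulmonary rate; visit→fill
lags; decoy visits; ICD-9/10 era split; census-proportional geography.

Not emulated: seasonality and secular trends, realistic NDC codes or
formulary behaviour, insurance churn (everyone is continuously enrolled
unless configured otherwise), correlated comorbidities, inpatient care, and
care-seeking behaviour that correlates visit timing with severity. Passing
recovery tests therefore demonstrates correctness of the *pipeline mechanics*
under the stated statistical structure, not fidelity to any real claims
population. In particular, subgroup contrasts (e.g. flagged-vs-unflagged
means) reflect the single calibrated pulmonary multiplier and need not match
published subgroup values that arise from richer correlation structure.

## Problem sizes and tolerances

Recovery tests run at 20 000–50 000 children (Monte-Carlo checks use 3
standard errors); the regression null-rate experiment uses 200 replicates of
1 500 children, and parameter recovery compares 100 replicates of 4 000
children against a 10⁶-child oracle fit. Calibration root-finding uses
bisection/Brent to |f| < 1e−10 with residual checks at 1e−6. The full test
suite completes in well under a minute on one CPU.
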