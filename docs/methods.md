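# Methods

This note documents the statistical machinery, the synthetic-registry
generative model, the numerical conventions, and the design choices made
where the problem left the design open. It states no empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## GA scales and the calibration constant k

Day 0 of every gestational-age scale is the first day of the last menstrual
period. The ultrasound scale is anchored by the registry-recorded GA at
birth; since GA advances one day per calendar day, GA on any earlier date and
the estimated date of delivery (day 283) follow by date arithmetic
(`ga_at_date`, `edd`). ART-based GA is `k + culture_days +
(transfer→birth)`, with `culture_days` counting fertilization→transfer for
fresh ET and fertilization→cryopreservation for frozen ET. `k` is a
parameter everywhere (`K14`/`K15` exposed); the identity
`diff(k) − diff(k+1) = 1` holds exactly per record, which is the entire
content of the 14→15-day recalibration. Registry-facing GA arithmetic is in
integer days; internal statistics (medians, CIs) use fractional days.

## Synthetic registry

The generator is a stated world, not a fit: its defaults are fixed a priori
and recovery tests measure the estimators against them.

- **Onset of birth.** Latent spontaneous-onset GA is skew-normal with shape
  −4 (left-skewed: more early than late outliers), scale ω = 16.58 chosen so
  the central 50% of onsets spans ≈ ±7 days, and location solved so the
  *median* equals the group parameter exactly (283/283/286 days). The median
  is the estimand throughout, so parameterizing by the median makes recovery
  unambiguous.
- **Follicular phase.** Shifted lognormal, median 15 days, 5th–95th
  percentiles ≈ 10–28 days (shift 6.875, log-sd 0.581): right-skewed because
  long cycles are more common than very short ones. Fertilization falls on
  LMP day F; ART transfers on day F + culture_days (for frozen ET this is the
  thaw-transfer timed culture_days after ovulation of the transfer cycle; the
  recorded fertilization date lies an arbitrary 30–365-day storage interval
  earlier).
- **Ultrasound error.** Gaussian, SD 2.5 days, rounded to whole days and
  truncated at 154 days (22 weeks), reflecting registry granularity. Note a
  consequence: with the follicular-phase spread above, synthetic pairwise
  GA_US − GA_ART differences have quartile offsets ≈ −3/+4 days — wider than
  real registries show, because real ultrasound dating partially absorbs
  ovulation-timing variation while the generator keeps the two independent.
  Synthetic-cohort tests therefore check calibration identities and medians,
  not the quartile spread of real data.
- **Interventions (right-censoring).** Two-part process: a potential
  intervention GA `I ~ Normal(276, 9)` (mass between ~260 days and term) and
  a Bernoulli realization with probability `p = target / P(round(I) <
  round(T))`, where the competition probability is computed by exact
  summation on the integer-day grid — so the expected nonspontaneous fraction
  equals the group target (30.7/35.5/44.1% by default) independently of the
  seed. The observed birth GA is `min(T, I)`; when `I` wins, the record is
  nonspontaneous. With `informative_censoring` on, the realization
  probability is scaled by `2·expit((T − median)/4)` so late onsets attract
  interventions, deliberately violating KM's independence assumption (used to
  demonstrate the resulting bias, not in defaults).
- **Onset types.** Nonspontaneous births split 74% induced, 24% elective
  cesarean, 2% pre-labor emergency cesarean (only the small emergency share
  is anchored; the induced/elective split is a plausible convention).
  `preeclampsia_fraction` (default 0.15 — pre-eclampsia is a leading
  indication for iatrogenic delivery) flags the competing-event label among
  nonspontaneous births.
- **What a green test does not establish.** The generator draws onset
  independently of the follicular phase, uses a single intervention-time
  distribution for all groups, and contains no covariate effects (maternal
  age, parity, fetal sex are carried but inert). Recovery under this world
  validates the estimators' correctness, not the clinical estimates of any
  real population.

## Survival machinery

- **Kaplan–Meier.** Product-limit over distinct observed days; at tied times
  events are processed before censorings (censored records remain at risk for
  that day's events). Greenwood's variance is accumulated on the log-S scale:
  `Var(log S(t)) = Σ d_i / (n_i (n_i − d_i))`, set to ∞ once S hits 0.
- **Medians.** The step median is the smallest observed time with
  S(t) ≤ 0.5. The interpolated median (default) applies a half-day
  continuity correction: the S-drop recorded at integer day d is spread
  linearly over [d − 0.5, d + 0.5), treating a recorded day as the
  nearest-day rounding of a continuous birth time. On day-grain data a naive
  step-point interpolation would sit ≈ 0.5 days below the continuous onset
  median; the corrected version is unbiased for it and yields the
  fractional-day medians registry analyses report.
- **Monte Carlo CIs.** Under asymptotic normality of log S near the median,
  each replicate adds a single standard-normal draw scaled by the monotone
  Greenwood SD profile to log S at the step times within ±10 days of the
  point median, restores monotonicity by a running-minimum (isotonic) pass,
  and re-extracts the interpolated median; the percentile interval of the
  replicate medians is reported (default n_sim = 10,000). Group differences
  perturb the two curves independently; each curve's random stream is keyed
  by the curve content plus the seed, which makes seed-matched comparisons
  exactly antisymmetric under argument swap. The construction is validated by
  coverage simulation (≥ 93% at nominal 95%) and by agreement with a
  nonparametric bootstrap of the KM median, not by matching any published
  interval digit-for-digit.
- **Censoring strategies.** `censor` (primary), `exclude` (drop
  nonspontaneous births) and `as_event` (treat them as spontaneous) are all
  available; the latter two systematically understate group medians and the
  understatement grows with the censoring fraction.
- **Competing risks.** Aalen–Johansen cause-specific cumulative incidence
  `CIF_k(t) = Σ_{t_i ≤ t} S(t_i−) d_{ki}/n_i` with overall survival from the
  any-cause KM; `Σ_k CIF_k + S = 1` holds to machine precision by
  construction and is asserted in tests.

## Agreement summaries

Medians and quartiles of pairwise differences use linear interpolation of
order statistics (numpy default); quartile *offsets* are reported relative to
the median. Absolute differences are rounded half away from zero before
binning into {≤1, 2, 3, 4, ≥5} days; percentages are printed to one decimal.
CIs for medians of differences use a seeded percentile bootstrap
(default B = 10,000) — assumption-light and verifiable by coverage; an
all-equal sample yields a zero-width interval rather than an error.

## Cohort rules

Exclusions run in a fixed order — multiple birth, perinatal death,
malformation, GA outside [154, 310] days, ART record with missing/ambiguous
dating — with each record counted at the first rule it trips, so the tally
conserves the input count even when flags overlap. Spontaneous onsets are
events; induced, elective-cesarean and pre-labor emergency-cesarean births
are censored.

## Numerical conventions and edge cases

- All randomness flows through explicit integer seeds; identical
  configuration gives byte-identical cohorts and report tables.
- An undefined median (S never reaching 0.5 under heavy censoring) raises,
  and the pipeline reports it as missing with the reason.
- `us_error_sd_days = 0` is accepted as the error-free limit used by the
  calibration identities, although realistic registries always have error.
- A censoring target unattainable by the intervention-time distribution
  (p > 1 after tuning) raises a parameter error rather than silently
  clipping.

## Known limitations

- The Monte Carlo CI perturbs log S with perfectly correlated draws across
  step times (a single Z scaled by the SD profile); the true correlation
  structure of the KM process is more complex, but the window is local and
  coverage validates the approximation at the sample sizes used here.
- The generator's intervention distribution is shared across groups; real
  obstetric practice differs by indication and group.
- Ultrasound-biometry modelling is out of scope: ultrasound GA at birth is an
  input field, as registries record it.
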