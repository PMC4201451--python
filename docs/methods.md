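# Methods

## Data model

A cohort is a set of patient trajectories, each a strictly time-ordered
sequence of EDSS measurements in years since assessed symptom onset (yso).
Admissible EDSS values are {0} ∪ {1.0, 1.5, …, 10.0}; 0.5 does not exist
on the scale.  The scale is treated as equal-interval only in 0–6.5, so
rate models default to records with EDSS ≤ 6.  When the year of onset is
known, a synthetic onset anchor (t = 0, EDSS 0) is prepended, encoding the
convention that relapsing-onset disease starts from a normal examination.
Records flagged `expected_midpoint` are derived quantities: they are
written to output files for inspection but regenerated, never trusted,
on input (re-loading the package's own artifacts is explicit opt-in).

Calendar dates are converted to yso with a 365.25-day year; a year-only
onset is resolved to mid-year (July 2).  Same-day repeat visits are an
input error rather than silently merged.  EDSS 10 (death due to MS) is
accepted by I/O but never forms an analysis endpoint and is excluded from
rate fits by the range filter.

## Irreversible endpoints and observation labels

Level *e* is an irreversible endpoint when some visit records EDSS ≥ *e*
and no later visit falls strictly below *e*; the attainment time is the
earliest visit from which the record never again drops below *e*.
Irreversibility is evaluated against the whole remaining follow-up — not a
confirmed-for-k-months window, which is a different (trial-style) notion
of sustained progression.  The implementation uses a suffix-minimum scan;
the test suite checks it against a literal quadratic transcription of the
definition on 10,000 fuzzed trajectories.

A visit is transitory (Ot, e.g. a relapse reading) exactly when a later
visit is strictly lower.  The remaining visits form a non-decreasing
sequence whose equal-value plateaus are labelled Of (first), Om
(intermediate) and Or (last repeat); the anchor is Oo.  For exhaustiveness
the plateau rule also covers non-transitory visits below EDSS 1, which sit
on the "level 0" plateau and never enter endpoint analyses.

## Survival-time assumptions

For an irreversible level with attainment time *t_b*:

* **maximum** — the event is placed at *t_b* (disability remains as last
  measured until the day of the next visit): slowest possible progression;
* **minimum** — the event occurs on the day of, but after, the last visit
  strictly below the level; it is represented numerically at that visit's
  time *t_a*, with no epsilon offset (path ordering is restored by sorting
  on level).  When onset is unknown and no earlier record sits below the
  level, the bracket is degenerate and the minimum time equals *t_b*;
* **midpoint** — the expectation of the censoring interval.  A maximal run
  of *k* consecutive grid levels first attained at the same visit shares
  the bracket (*t_a*, *t_b*], where *t_a* is the last record strictly
  below the run's lowest level (transitory highs therefore never shrink a
  bracket; in fact the bracket interior provably contains no visits at
  all).  The bracket is split into *k* equal subintervals with level *j*
  at t_a + (2j − 1)(t_b − t_a)/(2k).  For *k* = 1 this is the adjacent
  midpoint; the rule keeps every imputed time strictly inside the bracket
  and strictly increasing across levels.  The highest level of a skipped
  run is deliberately placed at its subinterval midpoint, strictly before
  the attaining visit, so that "midpoint survival time" applies to every
  endpoint uniformly.  When onset is unknown and the first bracket has no
  lower edge, no midpoint measure is generated for that run (logged); the
  affected levels enter models at their maximum time rather than inventing
  a left boundary.

This is deterministic midpoint expectation, not multiple imputation: no
stochastic draws from the censoring interval.  The modern nonparametric
alternative for interval-censored data — the Turnbull/NPMLE estimator — is
a conscious exclusion; the method here is midpoint imputation followed by
standard estimators, which is what it evaluates.

## Rate-of-change model

β_yso is the slope of EDSS on yso.  Because EDSS = 0 at onset is enforced
by the anchor, the default variant is pooled through-origin OLS
(statsmodels) on all records with EDSS ≤ 6; a per-patient-intercept
("within"/fixed-effects) variant is available behind a flag and demands at
least two records per patient.  Maximum-assumption fits use onset anchors
plus clinical observations; midpoint fits add the expected midpoint
measures; minimum fits add minimum-survival-time measures.  Transitory
(Ot) observations are clinical observations and are included by default,
with a flag to exclude them.

Uncertainty comes from a patient-level cluster bootstrap (default B = 999,
seed 20100): patients are resampled with replacement and the slope is
recombined from per-patient sufficient statistics (Σxy, Σx²), which
reproduces the OLS fit on each resample exactly and vectorises to
negligible cost.  95% intervals are percentile intervals.  Assumption
comparisons use a *paired* bootstrap — both slopes recomputed on the same
patient resample — and the speed-up 100·(β_mid − β_max)/β_max is flagged
significant when the percentile CI of the difference excludes zero.  Same
seed, same resamples, byte-identical results.

## Kaplan-Meier model

The probability of surviving an endpoint is p = 1 − f.  Estimation is
delegated to lifelines' product-limit estimator (hand-computed
product-limit arithmetic serves as the independent oracle in tests);
events precede censorings at tied times.  Event times come from path
construction under the chosen assumption; patients who never irreversibly
reach a level are right-censored at their last clinical observation under
*every* assumption — midpoint adjustment never moves censoring times.
Default endpoint set is integer EDSS 1–9, configurable to the half-point
grid.  Median survival is the smallest event time with S ≤ 0.5 (undefined
when the curve never crosses 0.5).  Point curves are the primary output;
Greenwood-type 95% bands are available behind a flag.  The synthetic
onset cohort filter keeps patients with a known onset and a minimum number
of clinical observations; the default minimum is 2 (a stricter minimum of
3 is a sensible alternative for survival analyses and is a config value).

## Censoring-bias metrics

Assessment rates are records per patient-year, pooled as total records /
total person-years (ratio of sums); per-patient mean-of-ratios is emitted
alongside because "per patient per year" admits both readings, and the
two can differ materially when window lengths vary.  Windows are first-to-
last or onset-to-last clinical observation; onset anchors are never
counted as observations.  Patients with a single clinical visit have a
zero-length first-to-last window and are excluded from that basis (logged)
but kept onset-to-last.  Under obs+Exp counting the onset-to-first gap
uses the patient's first expected midpoint measure when one exists — the
earliest moment the record places any disability.  The censoring partition
splits (onset, horizon) into left / interval / right windows; the right
window is reported only when an analysis horizon is supplied, and the left
window is undefined without a known onset.  Era reports restrict records
to inclusive calendar windows via onset year + yso; a patient contributes
to every era in which they have an observation, so era rows are not
disjoint.

## Synthetic cohort generator

The generator emulates the statistical structure the analysis assumes:

| parameter | default | meaning |
|---|---|---|
| `beta_true` | 0.17 EDSS/yr | latent linear progression rate (the estimand) |
| `beta_sd` | 0 | per-patient gamma rate heterogeneity |
| `visit_gap_mean`, `visit_gap_shape` | 2 y, 2 | gamma renewal visit gaps |
| `onset_delay_mean` | 2.5 y | exponential onset-to-first-visit delay |
| `followup_mean`, `followup_shape` | 20 y, 10 | gamma follow-up horizon |
| `relapse_rate` | 0.5 /yr | Poisson relapse arrivals |
| `relapse_height`, `relapse_duration_mean` | +1.0, 0.15 y | transitory elevation observed if a visit falls in the window |

Latent disability D(t) = min(β·t, 10) is floored to the last attained grid
level — an endpoint counts as reached only once latent disability attains
it — and the first clinical visit occurs exactly at the onset delay, so
`onset_delay_mean` is the estimand of the onset-to-first censoring metric.
Defaults describe a natural-history clinic population: ~0.45 assessments
per patient-year onset-to-last, onset-to-first gaps of a few years, most
patients followed around two decades, and enough relapse activity that
transitory (Ot) readings occur.  Visit gaps are gamma because the only
firm constraint is irregular positive gaps with controllable mean and
variance; nothing in the analysis depends on that family.

What the generator deliberately omits: visit frequency correlated with
disability or relapses (informative observation), covariate effects,
secondary-progressive change-points, a death process, and measurement
noise beyond grid flooring and relapse elevations.  Passing tests
therefore demonstrate correctness of the pipeline and the *directional*
properties of the assumptions (midpoint faster than maximum, recovery of a
known rate, bracketing of true crossing times) — not that real clinic data
satisfy the generator's independence assumptions.

## Known limitations

Two qualitative expectations about midpoint adjustment hold for the real
motivation but are *not* theorems of the estimators, and the test suite
documents both:

* **Pointwise KM dominance can fail in sparse-event tails.**  Midpoint
  event times are never later than maximum ones and censoring is shared,
  yet S_mid(t) ≤ S_max(t) for all t is not guaranteed: when an event moves
  before another patient's censoring time, the product-limit risk sets
  reorganise, and at levels reached by only a handful of patients the
  midpoint curve can sit *above* the maximum curve late in follow-up (in
  the extreme, a single event that is the latest observation drives the
  maximum curve to zero while the midpoint curve retains the censored
  mass).  Dominance is exact whenever no censoring time interleaves the
  shifted events — e.g. in fully-followed cohorts, where both curves are
  empirical survival functions — and medians remain well ordered; the
  discrepancy lives exactly where heavy right-censoring already makes the
  curves unreliable.
* **Era-to-era variability reduction needs informative visit processes.**
  With a linear latent process measured exactly at visit dates and visit
  timing independent of disability, the maximum-assumption pooled slope is
  insensitive to visit frequency (its only bias is the grid-floor lag of
  about a quarter step, which does not depend on gap length), so sparse-
  and dense-assessment eras produce nearly identical maximum estimates,
  and midpoint adjustment — whose correction is gap-sized — cannot shrink,
  and in fact adds, cross-era dispersion.  The variability reduction seen
  in real clinic data rests on mechanisms the generator deliberately
  excludes (visit frequency tracking disability, era-varying patient mix
  and referral patterns).  The dispersion report is still the right tool
  on real data; the synthetic cohort simply cannot exhibit the phenomenon.

Other numerical choices: bootstrap percentile CIs are clamped to contain
the point estimate; degenerate bootstrap resamples with zero slope
denominator are dropped from the percentile computation; all seeds are
explicit with fixed defaults, and every pipeline run records its seeds and
record counts in a JSON manifest.
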