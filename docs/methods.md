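# Methods

## The utilization model

All schedule arithmetic is done in integer minutes from midnight with
half-open intervals `[start, end)`; rates are formed only at the end.
This makes back-to-back slots unambiguous, keeps every sum exact, and
lets the pointwise identity `LUR = LUR_T + LUR_NT` hold to machine
precision on every record (note that medians of `LUR_T` and `LUR_NT`
over a period need *not* sum to the median `LUR`; only the pointwise
identity is asserted).

Per linac-day:

* `OH1` — opening window length. Windows are configured per weekday
  (Mon–Fri); weekends are outside the operating calendar and an optional
  holiday list removes further dates. Events spanning midnight are
  rejected; they cannot occur within a 06:45–16:15 operation.
* `HT` — minutes of the `Pre-booked` and `Treatment` subcategories,
  counted inside *and* outside the opening window, excluding slots
  flagged as no-shows. Pre-booked placeholder slots count as treatment
  time because they represent linac time dedicated to (future) patients;
  a separate `HT_prebooked` field supports the pre-booked share metric
  `LUR_prebooked = 100·HT_prebooked/OH1`.
* `HNT` — non-treatment minutes clipped to the opening window.
  Non-treatment activity outside opening (e.g. evening QA) is ignored by
  construction, so `LUR_NT ≤ 100` always, while `LUR_T` may exceed 100
  via outside-opening treatment minutes.
* `OH2` — all scheduled minutes outside the opening window, any
  category.
* No-show slots never contribute to `HT`; their minutes are tracked
  separately and reported weekly as a share of the park's weekly opening
  hours, rounded to 0.1%.

**Aggregation.** The default is *pooled*: hours are summed over the
member linacs and the rates recomputed from the sums, i.e. the group
behaves as one super-linac. This is the natural reading of a time ratio
and makes the park row of the daily view exactly consistent with its
linac rows. An unweighted *mean-of-linacs* alternative is provided
(`method="mean_of_linacs"`) for users who want each linac to count
equally regardless of its opening hours; with identical windows the two
coincide.

**Planned vs observed comparison.** Daily paired series are compared
with the Wilcoxon signed-rank test, two-sided. Zero differences are
dropped (classic zero handling rather than Pratt's), tied absolute
differences receive mid-ranks, the exact null distribution is used for
n ≤ 25 pairs without ties and the normal approximation with continuity
correction otherwise. Period summaries report mean, SD (n−1
denominator), median and range; views round percentages to integers at
render time only.

## Day-0 deviation analysis

A day's *planned* snapshot (captured at the morning snapshot time,
default 06:00) and *observed* snapshot (21:00) are compared through
per-subcategory minute deltas (observed − planned), using the same
clipping rules as the metrics (non-treatment clipped to opening,
treatment counted in full net of no-shows). Classification is exact: a
rate counts as increased iff its underlying minute delta is positive —
no epsilon, since minutes are integers. A record "deviates" when any of
the three rates changed; this definition is documented because a
schedule edit that leaves all three rates unchanged (e.g. moving a slot
within the day) does not count as a deviation here.

Non-treatment increases above a threshold (0, 2 or 5 percentage points,
tested exactly as `100·Δminutes > threshold·OH1minutes`) are attributed
to the single non-treatment subcategory with the largest positive minute
delta. Ties are broken by a fixed order — Maintenance, PatientQA,
LinacQA, Preparation, Meetings, Education, Break — reflecting that large
disruptions are typically machine downtime and small ones patient-plan
QA. Attribution sets nest across thresholds by construction. Because the
natural denominator of an attribution rate is ambiguous, the summary
table reports both: per all linac-days and per attributed linac-days.

## Prospective horizon analysis

Each morning snapshot covers Day 0 plus the following `H` weekdays
(default 100). For a snapshot taken on date *d*, the metric evaluated on
the schedule of the date *h* weekdays ahead contributes one observation
to horizon point *h*; pooling an archive gives mean ± SD curves with
SD = 0 flagged via n = 1 where only one snapshot contributes. The curve
is fitted by least squares with a polynomial in *h* (default degree 4,
overridable; degree ≥ 3 is needed for an interior second-derivative
root, and degree 5 is recommended for logistic-shaped fill curves whose
odd symmetry a quartic cannot capture — the tests and the acceptance
script use 5).

The horizon axis points *away* from the present (h = 0 is today), so
utilization *rises* as h decreases and the booking build-up rate is
−P′(h). The steepest-build-up day is located at the real roots of P″
inside the range at which −P′ has a local maximum (P‴ > 0), falling back
to the range endpoints when no such root exists (e.g. monotone fits);
ties go to the smallest h and an `interior` flag records whether the
result sits on an endpoint. Restricting candidates to local maxima
avoids spurious endpoint answers caused by polynomial edge oscillation.

`max_metric_day` returns the h with maximal mean (ties toward smallest
h). `transition_day(series, level)` scans the pre-booked share upward
from h = 0 and returns the largest h still ≤ the level before the first
exceedance; a series that never exceeds the level returns the horizon
end with a warning.

## The synthetic department

The simulator emulates the statistical structure of a real scheduling
archive; its defaults describe the modelled clinic.

* **Machine park**: eight linacs in three treatment-equivalent groups;
  four open 07:00–16:15 (9.25 h/day, 46.25 h/week) and four 06:45–16:15
  (9.5 h/day, 47.5 h/week) — 375 opening hours per week.
* **Referrals**: Poisson stream, default 14 patients/weekday (sized so
  steady-state treatment load plus the pre-booked share fills ~85% of
  the park). Each series has 1 + Poisson(11.2) fractions (mean 12.2) on
  consecutive weekdays with one 15–20 min slot per day, and a diagnosis
  group drawn from a fixed categorical.
* **Booking**: greedy earliest-feasible placement of the *whole* series
  on one linac of one group (a series must fit entirely); infeasible
  series within the horizon are deferred and ledgered, never
  double-booked. The booking lead time of the first fraction is drawn
  from a logistic distribution (midpoint 50 weekdays, scale 8) and the
  series is centred on the drawn lead so that the mean slot lead matches
  the fill model despite fractions trailing the series start. Seen from
  h weekdays out, occupancy then traces a logistic fill curve whose
  steepest-growth day equals the configured midpoint; under heavy load
  greedy displacement adds a small (≲1 day) upward bias.
* **Pre-booked placeholders**: each linac-day holds ~20% of OH1 in
  care-path placeholder slots created before the archive begins. Each
  converts to a scheduled treatment at a logistic horizon (midpoint 30,
  scale 6.8), chosen so the mean pre-booked share is ~20% at h = 100,
  declines from ~day 50 and crosses 1% near h = 10; all placeholders
  have converted by Day 0.
* **Non-treatment baseline**: fixed daily blocks (default morning linac
  QA 20 min, midday break 15 min, afternoon meeting 10 min = 45 min,
  i.e. 7.9–8.1% of opening) at fixed anchor times — a deliberately flat
  LUR_NT profile across the horizon.
* **Day-0 perturbations**, applied to the morning plan in a fixed order
  per linac for reproducibility: (1) a maintenance/downtime block
  (default probability 0.05/linac-day, 120 min, random 5-min-aligned
  start) displacing whatever it overlaps, with displaced patient slots
  cancelled; (2) a patient-QA insertion (probability 0.35, 10 min) into
  the first sufficiently large free gap; (3) independent treatment
  cancellations (probability 0.03/slot); (4) no-show flagging with
  per-slot probability `no_show_rate·OH1/HT`, so the expected flagged
  time is the configured share of opening hours (default 0.6%).
  Probabilities were set so that small non-treatment increases are
  mostly patient QA and large ones maintenance.
* **Determinism**: one master `SeedSequence` spawns independent streams
  for referrals, placeholders, booking and perturbation; the same
  parameters and seed give byte-identical archives. Every injected
  event, booking lead, deferral and no-show is recorded in a ground-truth
  ledger (JSON-lines on disk).

What the simulator does *not* model: staff rosters, vacation-period
capacity changes, correlated cancellations, patient transfers between
groups mid-series, special techniques, or slot-time misestimation
(scheduled time is taken at face value). Passing tests therefore show
that the analysis recovers the structure the generator injects, not that
a real department behaves this way.

## Problem sizes and numerical choices

The test suite and the acceptance script exercise a two-linac slice of
the department over 120–200 snapshot weekdays with ~3 referrals/weekday
— the full booking, conversion and perturbation dynamics at a size that
runs in seconds. Oracle checks (minute-grid enumeration, pairwise
overlap, Wilcoxon sign-assignment enumeration, pooled-union
recomputation) use 100–10,000 random linac-days. Percentages are
rounded half-away-from-zero using exact rational arithmetic; polynomial
fits use `numpy.polynomial` least squares; statistical checks on
stochastic quantities use 3·SE bands.

Known limitations: the steepest-increase estimate inherits the bias of
the chosen polynomial degree (a quartic misplaces a logistic inflection
by several days; degree 5 is adequate); `transition_day` assumes the
pre-booked series is monotone apart from noise; the overlap validator
treats any same-linac intersection as an error with no merge heuristic
for dirty exports.
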