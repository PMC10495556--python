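# Methods

## Deterministic demand-capacity model

The model is an average-flow balance over discrete review periods. Demand
`D = Σ f·p·(N + A)` counts expected review-plus-contact events per period;
capacity `K = (60/t)·m·h` counts deliverable reviews per period. Each
contact event is costed at a single average duration `t`, covering both the
data review and any asynchronous message; synchronous phone or video time is
out of scope, as is per-provider heterogeneity (one pool, one average rate).

**Coverage direction and cap.** Coverage is defined as capacity over demand,
`100·K/D`, not the reverse: only this direction is consistent with coverage
rising when reviews get faster and saturating at 100% when capacity exceeds
demand. The uncapped ratio is retained (`raw_coverage`) because scenario
sufficiency must be judged on it — the capped value saturates at exactly 100
and cannot distinguish "just enough" from "ample". Reported values are
rounded half-up to integer percent; full precision is kept internally. Zero
demand is defined as 100% covered (nothing to cover) with the raw ratio
recorded as infinite rather than raising.

**Units.** The review period is the time unit, one week by default. A
monthly cadence inside weekly periods is `f = 0.25` (4 weeks/month); users
preferring the calendar average can pass `1/4.345`. The per-provider review
rate is derived as `60/t` so that review-time scenarios are expressible; a
`review_capacity_override` accepts a direct patients-per-hour figure, which
disables the review-time axis (capacity no longer depends on it).

**Population projection.** `N(k+1) = N(k)·(1−g) + A`: graduation applies
before enrolment within a period. The alternative ordering differs by
`O(g·A)` per period and nothing in the use cases distinguishes them; with
`g > 0` counts converge to the fixed point `A/g`, with `g = 0` growth is
exactly linear.

**Anchored scenarios.** Clinics often know their reported coverage but not
their absolute demand. `Scenario.from_reported_coverage` back-solves
`D = 100·K/coverage` and represents it as a single cohort with `f = p = 1`,
so all six modification axes remain available and coverage scaling is exact.

## Scenario explorer

Single-axis what-ifs recompute coverage with exactly one input changed;
deltas are differences of *reported* (integer) percentages, since that is
how a dashboard quotes them. The closed-form sufficiency solvers invert the
capacity equation: `m* = ⌈D·t/(60·h)⌉`, `t* = 60·m·h/D`, `h* = D·t/(60·m)`;
demand-side axes use the linearity of `D` in `p`, `f` and the population.

Sufficiency values are snapped to grids, always toward more capacity:
integers for providers and population (populations round down), 0.1 for
hours and minutes (the granularity of a staffing slider), and 0.01 for the
contact fraction and review frequency — a 0.1 step on a quantity bounded by
1 would be coarser than the quantity itself. A guard of 1e-9 absorbs
floating-point ties at exact boundaries. Axes that cannot reach full
coverage alone are flagged `unreachable`; when the baseline already meets
demand every row is `already_covered`. Cohort-level axes require a uniform
baseline value across cohorts (otherwise no single-axis change exists; the
table flags such rows `not_applicable` instead of failing). There is no
cross-axis optimization: the table answers "what would it take on this
lever alone".

## Workload simulator

Motivation: the deterministic model is an average and says nothing about
week-to-week fluctuation. Per period the simulator draws, in fixed order
from one seeded `numpy` generator, (1) flagged counts per cohort from
`Binomial(shown, flag_probability)` where `shown = round(f·N(k))` follows the
population projection, and (2) one contacted/flagged ratio from a Normal
truncated to [0, 1]. Contacts are `round(flagged · ratio)`. The ratio is
drawn **once per period, not per patient**: the calibration target is the
dispersion of a period-level ratio (SD ≈ 17 percentage points), and
per-patient Bernoulli thinning would shrink that dispersion toward the
Binomial limit, badly understating it.

Contacts beyond capacity join a FIFO backlog served before new contacts in
later periods. `shortfall` records the new contacts deferred in a period and
`backlog` the cumulative deferred total; cumulative contacted equals
cumulative served plus final backlog by construction (the conservation
property the tests enforce on every replicate). Capacity may be fractional;
counts are integers; rounding of expected shown counts is half-up, with a
Poisson alternative behind `shown_draw="poisson"` for users who prefer
integer-noise enrolment.

Defaults: ratio mean 0.518 and SD 0.171, the study-period calibration of the
reference program (March 2020 – April 2022). At this calibration the [0, 1]
truncation is mild — 0 is 3.0 SD and 1 is 2.8 SD from the mean — shifting
the mean by < 0.1 points and shrinking the SD to ≈ 16.8 points; recovered
statistics are expected to show this shrinkage.

## Historical logs and calibration

Logs are CSV with the exact header `period_start,shown,flagged,contacted`,
ISO dates in strictly increasing order, and integer counts obeying
`contacted ≤ flagged ≤ shown`; the loader reports the first offending line.
Dates are labels only — no gap detection or calendar arithmetic.

Ratio statistics use per-period `contacted/flagged` over periods with
`flagged > 0` (the ratio is undefined otherwise; the excluded count is
reported), with the sample (n−1) SD — at ~100 weekly periods the n vs n−1
difference is below the one-decimal reporting precision, which matches how
such ratios are quoted. Calibration fitting adds
`flag_probability = mean(flagged/shown)` over periods with `shown > 0`.
Projection-versus-actual evaluates `Σ f·p·(N(k)+A)` per period against
actual contacts and summarizes with MAPE over periods with nonzero actuals.

## Synthetic-data generator

The generator emulates the reference program's published operational
statistics: a shown-for-review count with steady growth (linear by default,
logistic behind `growth_model="logistic"` for saturating programs), Binomial
flagging, and the truncated-normal period ratio. Defaults — 200 patients
shown initially, +1/week, flag probability 0.3 — give flagged counts in the
tens per week growing steadily, the scale of the reference program's
reported quarterly flagged counts (26→47 over six months). The flag
probability is a free parameter the reference program never published; 0.3
is a realistic choice for a tuned flagging algorithm and is recoverable from
any real log via `fit_calibration`.

What the generator deliberately does **not** emulate: autocorrelation in
flagging (repeat-flag patients), seasonal or holiday effects, calendar gaps,
enrolment shocks, and any dependence of the contact ratio on the flagged
count. Passing calibration-recovery tests therefore shows the pipeline is
statistically self-consistent, not that real logs satisfy these
independence assumptions. The baseline scenario preset leaves contact
fractions as explicit null placeholders because the reference program never
published its baseline value; silently defaulting would fabricate a key
input, so loading fails until the user supplies one.

## Problem sizes and numerical choices

Calibration-recovery checks use 110-period logs across 20 seeds (matching a
two-year weekly log) plus 500- and 10,000-period runs for parameter
recovery; solver-versus-grid-search equivalence uses 200 randomized
scenarios. Monte-Carlo tolerances follow from the ratio SD: the per-seed
mean of 110 periods has SE ≈ 1.6 points, a 10,000-period mean ≈ 0.17
points. All stochastic tests fix seeds; same config + seed reproduces
simulator output and generated logs byte for byte.

## Known limitations

- Averages-in, averages-out in the deterministic layer: no within-period
  queueing discipline beyond FIFO backlog, no patient-level state.
- Contact fraction is static per scenario; programs whose intervention
  lowers it over time should rerun with updated values.
- One provider type; heterogeneous pools need one scenario per type.
- The backlog policy assumes deferred contacts remain worth making a period
  later, which may not hold clinically for urgent flags.
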