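# Methods

`screenbouts` turns raw smartphone power-state logs into screen-time
measures for digital-phenotyping studies. This note documents the models
and heuristics the package implements, the choices made where the problem
was genuinely underdetermined, and what the synthetic-data tests do and do
not establish.

## The data and its failure modes

Passive sensing apps (Beiwe-style) record, with millisecond UTC
timestamps:

* **iOS** — `Unlocked` / `Locked` events, plus one battery event for every
  1% change in charge level;
* **Android** — `Screen turned on` / `Screen turned off` events, with no
  battery telemetry.

Two failure modes dominate. First, the OS suspends the logging app, so
events are silently missing: an unlock without a matching lock, or hours of
nothing. Second, Android screens wake briefly on notification arrival with
no user interaction, producing spurious short "use" events.

## Bout extraction

A *screen-on bout* is a maximal half-open interval `[start, end)` of
consecutive screen use. The default extraction:

1. **Pairing with imputation.** A state machine walks the open/close
   sequence. An open while a bout is already open closes the current bout
   at the new open's timestamp (flagged `close_imputed`) and starts a new
   one — the next unlock is the tightest available upper bound for the lost
   lock. A close with no open bout is dropped: the open time cannot be
   bounded from the left without inventing data. A bout still open at
   end-of-stream is closed at `start + cap` when a cap is configured and
   dropped otherwise.
2. **Notification filter (Android only).** Bouts shorter than
   `notification_min_seconds` (default 10 s) are removed. The threshold is
   a package choice: logs do not label notification wakes, and screen-wakes
   too short for meaningful interaction are the plausible target. iOS
   unlocks require interaction, so no filter applies.
3. **Capping.** Bouts longer than `cap_minutes` (default 30, roughly the
   97th percentile of observed bouts) are truncated, bounding the
   overestimation that imputation can cause.

The filter runs before the cap: capping cannot create short bouts, so the
order is safe and the cap keeps the last word on duration.

Three comparator modes bracket sensitivity: `comparator1` (impute, 6 h
cap), `comparator2` (no imputation — only adjacent open/close pairs — and
no cap), `comparator3` (no imputation, 30-min cap). For any fixed stream,
total screen time is monotone in the cap: cap30 ≤ cap360 ≤ uncapped.

## Validity labeling

Screen-time measures are only trusted on days with adequate log coverage.

**iOS.** The battery stream is an app-liveness heartbeat. A minute is
*valid* iff (criterion 1) it lies in a gap of ≤ 60 minutes between
consecutive battery events — events fire per 1% change, so spacing ≤ 60 min
is exactly a ≥ 1%/hour rate — or (criterion 2) it lies within 12 hours
after a 100% battery event with no intervening sub-100% event (phone
sitting on the charger, battery flat at 100%, hence no events despite the
app being alive). Criterion 2 terminates at the first sub-100% event
because a level drop means discharge resumed and criterion 1 takes over;
repeated 100% events restart the window. The minute containing a
qualifying event is valid (half-open minute convention). A *valid day* has
≥ 1080 valid minutes (18 h).

**Android.** No battery telemetry, so valid minutes are undefinable; a
*valid day* has screen-on bouts overlapping ≥ 8 distinct hours. Hour
membership is by interval overlap (a 07:30–09:30 bout contributes hours 7,
8 and 9), chosen over start-hour-only because a bout's presence in an hour
is evidence of logging in that hour regardless of where it started.

**Analysis sample.** A valid day is retained iff some 28-consecutive-day
window containing it holds ≥ 14 valid days; a participant is retained with
≥ 28 retained days. Windows slide by calendar day over the observation
span (least arbitrary, given no stated anchoring) and are clipped at the
span edges, which only makes the criterion stricter at the margins.

## Daily and minute-level measures

Days are midnight-to-midnight UTC. Bouts are split at UTC midnight and
fragments are attributed to their day, making the conservation identity
exact (`Σ daily totals = Σ bout durations`). Per valid day:

* `total_on_minutes` — sum of fragment durations;
* `on_bout_count` — number of fragments, and `log_on_bout_count = ln(count)`
  (undefined for zero-bout days; no +1 offset is invented, so the measure
  is absent there);
* `mean_on_bout_minutes = total / count`;
* `mean_off_bout_minutes` — mean of the *interior* gaps between consecutive
  fragments. Gaps touching the day boundary are censored intervals and are
  excluded, so days with ≤ 1 fragment have no off-bout mean. This is one
  admissible reading; the original day-assignment rule for off-bouts is not
  auditable without the data.

The minute grid assigns each half-open minute its overlap (0–60 s) with
the bouts; `binary_on = 1` iff any screen-on time fell in the minute.
Cohort summaries align participants on their first observed day and report
the 10/25/50/75/90th percentiles per relative day, smoothed with a
centered 7-day moving average (edges use the available window).

## DST design and the pointwise estimator

A daylight-saving transition is a sudden exogenous shift of the local
clock, a natural experiment on sleep and phone-use timing. The design
takes all participant-days within ± `window_days` (default 14; 7 and 28
for sensitivity) of the transition's UTC date, excluding the transition
day itself (internally inconsistent in local time), with a scalar `post`
indicator.

The package deliberately does **not** implement functional mixed-model
inference. `pointwise_logodds` computes, per minute, the empirical
screen-on proportions in the pre and post groups and returns
`log[(p1/(1−p1)) / (p0/(1−p0))]`, clipping proportions to
`[0.5/n, 1 − 0.5/n]` as a continuity correction. It ignores
within-participant correlation, so it is a sign- and magnitude-recovery
device for simulated data, not an inferential estimator; reported effects
convert to odds ratios via `exp`.

## The simulator as a stated world

`synthetic.SimParams` defaults describe one realistic participant, chosen
once against published cohort plausibility ranges (≈ 250–270 min/day in
≈ 50–60 bouts of ≈ 4–5 min, off-bouts ≈ 25 min):

| parameter | default | meaning |
|---|---|---|
| `sleep_start_local`, `sleep_end_local` | 23:00, 07:00 | local sleep interval (16 wake hours) |
| `tz_offset_hours` | −5 | fixed UTC offset (US Eastern standard) |
| `bout_rate_per_wake_hour` | 4.5 | Poisson candidate-start rate; overlap thinning leaves ≈ 50 bouts/day |
| `bout_duration_lognormal` | (5.2, 1.0) log-s | median ≈ 3 min, mean ≈ 5 min |
| `battery_drain_pct_per_hour` | 5 | linear drain while off the charger |
| `battery_charge_pct_per_hour` | 30 | linear overnight charge to 100%, then flat |
| `notification_wake_rate_per_hour` | 1 (Android) | 5-s screen wakes around the clock |
| `dst_sleep_shift_minutes` | 0 | sleep-schedule shift after `dst_transition_ms` |

Bout starts are a Poisson process over wake minutes; a start inside an
active bout is discarded (thinning), which preserves Poisson-like starts
while guaranteeing non-overlapping truth. Battery events are emitted at
integer-percent crossings of a piecewise-linear trajectory, mirroring the
per-1%-change logging. Local time is a fixed UTC offset plus an explicit
sleep-shift parameter rather than tz-database semantics, keeping the clock
model transparent. Dropout deletes events inside given windows while the
truth is kept for recovery scoring.

What the simulator does *not* emulate: weekday/weekend structure, within-
day nonstationarity of use intensity, charging-habit variability, battery
nonlinearity, device swaps, or clock skew. A green recovery test therefore
establishes that the pipeline is a correct inverse of the stated
generative process — not that the heuristics are well calibrated for any
particular real cohort.

## Numerical conventions

* All timestamps are integer epoch milliseconds UTC; minutes, hours and
  days are half-open intervals.
* Zero-length bouts are dropped everywhere; bout sequences are sorted and
  non-overlapping by construction.
* Duplicate event timestamps are preserved; stable sorts keep file order.
* Undefined measures (off-bout mean with < 2 fragments, log of a zero
  count) are NaN, never 0.
* Conservation identities hold to 1e-9 in float minutes; recovery of
  simulated truth is exact in integer milliseconds.

## Known limitations

* The imputation and notification rules are one admissible reading of
  underdocumented preprocessing; comparator modes exist precisely to
  expose sensitivity to them.
* iOS and Android validity criteria are not harmonized in strictness;
  cross-OS comparisons of valid-day counts reflect the heuristics as much
  as the phones.
* `pointwise_logodds` is not an inferential procedure (no confidence
  bands, no random effects); use a functional GLMM for real analyses.
* UTC-only day boundaries: a "day" is not the participant's local day.
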