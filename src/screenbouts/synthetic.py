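"""Ground-truthed phone-state log simulator.

Every pipeline stage is tested against simulated participants because no
deposited raw logs exist.  The generator emulates the statistical structure
the pipeline assumes:

* a sleep/wake schedule on a local clock (fixed UTC offset, no tz-database
  semantics — the clock model stays transparent and testable), with an
  optional one-off sleep shift after a DST transition instant;
* screen-on bouts starting as a Poisson process during wake hours with
  lognormal durations, made non-overlapping by thinning (a start inside an
  active bout is discarded);
* iOS battery telemetry: one event at every integer-percent crossing of a
  piecewise-linear charge trajectory (overnight charging to 100%, then flat
  on the charger until wake, then linear drain);
* Android notification wakes: short fixed-duration screen-on events at a
  Poisson rate around the clock, flagged in the truth so recovery tests can
  separate them from actual use;
* log-dropout missingness injected by deleting events inside given windows
  while leaving the truth untouched for recovery scoring.

Defaults are calibrated to published cohort plausibility ranges for daily
screen time (roughly 4-4.5 h/day in 50-60 bouts of ~4-5 min).  Identical
``(params, seed)`` always reproduce identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .bouts import Bout
from .errors import ContractViolationError
from .state_logs import OS, EventKind, EventRecord, EventStream
from .validity import ios_valid_days, ios_valid_minutes, android_valid_days

__all__ = ["SimParams", "SimOutput", "simulate_participant", "inject_dropout", "simulate_dst_cohort"]

MS_PER_MINUTE = 60_000
MS_PER_HOUR = 3_600_000
MS_PER_DAY = 86_400_000


@dataclass(frozen=True)
class SimParams:
    """Simulation settings for one participant.

    Sleep is the local-clock interval ``[sleep_start_local, sleep_end_local)``
    in minutes of day (wrapping midnight); local time is UTC plus
    ``tz_offset_hours``.  When ``dst_transition_ms`` is set, the sleep
    schedule shifts by ``dst_sleep_shift_minutes`` for all instants at or
    after the transition.
    """

    os: OS = OS.IOS
    n_days: int = 30
    start_utc: str = "2021-01-04"
    sleep_start_local: int = 1380  # 23:00
    sleep_end_local: int = 420  # 07:00
    tz_offset_hours: float = -5.0
    bout_rate_per_wake_hour: float = 4.5
    bout_duration_lognormal: Tuple[float, float] = (5.2, 1.0)  # log-seconds
    min_bout_seconds: float = 1.0
    max_bout_seconds: Optional[float] = None
    battery_start_pct: float = 85.0
    battery_drain_pct_per_hour: float = 5.0
    battery_charge_pct_per_hour: float = 30.0
    charge_sessions_per_day: float = 1.0
    notification_wake_rate_per_hour: float = 1.0
    notification_wake_seconds: float = 5.0
    dropout_windows: Tuple[Tuple[int, int], ...] = ()
    dst_sleep_shift_minutes: float = 0.0
    dst_transition_ms: Optional[int] = None
    seed: int = 0
    participant_id: str = "sim-001"

    def __post_init__(self) -> None:
        object.__setattr__(self, "os", OS(self.os))
        if self.n_days <= 0:
            raise ContractViolationError("n_days must be positive")
        if self.sleep_start_local == self.sleep_end_local:
            raise ContractViolationError("sleep interval must be non-degenerate")
        for name in (
            "bout_rate_per_wake_hour",
            "battery_drain_pct_per_hour",
            "battery_charge_pct_per_hour",
            "charge_sessions_per_day",
            "notification_wake_rate_per_hour",
        ):
            if getattr(self, name) < 0:
                raise ContractViolationError(f"{name} must be >= 0")
        if self.bout_rate_per_wake_hour == 0 and self.notification_wake_rate_per_hour == 0:
            pass  # degenerate but allowed: produces an empty screen-event stream
        if self.notification_wake_seconds <= 0:
            raise ContractViolationError("notification_wake_seconds must be positive")

    @property
    def start_ms(self) -> int:
        return int(pd.Timestamp(self.start_utc, tz="UTC").value // 10**6)

    @property
    def end_ms(self) -> int:
        return self.start_ms + self.n_days * MS_PER_DAY


@dataclass(frozen=True)
class SimOutput:
    """Simulated stream plus the ground truth it was generated from."""

    stream: EventStream
    truth_bouts: Tuple[Bout, ...]
    truth_valid_days: pd.Series
    params: SimParams


def _sleep_interval(params: SimParams, t_ms: float) -> Tuple[float, float]:
    s, e = float(params.sleep_start_local), float(params.sleep_end_local)
    if params.dst_transition_ms is not None and t_ms >= params.dst_transition_ms:
        s = (s + params.dst_sleep_shift_minutes) % 1440
        e = (e + params.dst_sleep_shift_minutes) % 1440
    return s, e


def _is_wake(params: SimParams, t_ms: float) -> bool:
    s, e = _sleep_interval(params, t_ms)
    local_minute = (t_ms / MS_PER_MINUTE + params.tz_offset_hours * 60.0) % 1440
    if s < e:
        asleep = s <= local_minute < e
    else:
        asleep = local_minute >= s or local_minute < e
    return not asleep


def _poisson_times(rng: np.random.Generator, rate_per_hour: float, t0: int, t1: int) -> np.ndarray:
    if rate_per_hour <= 0:
        return np.empty(0)
    span_hours = (t1 - t0) / MS_PER_HOUR
    n = rng.poisson(rate_per_hour * span_hours)
    return np.sort(rng.uniform(t0, t1, size=n))


def _draw_bout_candidates(params: SimParams, rng: np.random.Generator) -> List[Tuple[int, int, bool]]:
    """(start_ms, end_ms, is_notification) candidates before overlap thinning."""
    mu, sigma = params.bout_duration_lognormal
    starts = _poisson_times(rng, params.bout_rate_per_wake_hour, params.start_ms, params.end_ms)
    durations = rng.lognormal(mu, sigma, size=len(starts))
    durations = np.maximum(durations, params.min_bout_seconds)
    if params.max_bout_seconds is not None:
        durations = np.minimum(durations, params.max_bout_seconds)
    min_ms = max(1000, int(round(params.min_bout_seconds * 1000)))
    cands = [
        (int(t), int(t) + max(min_ms, int(round(d * 1000))), False)
        for t, d in zip(starts, durations)
        if _is_wake(params, t)
    ]
    if params.os is OS.ANDROID and params.notification_wake_rate_per_hour > 0:
        notif = _poisson_times(
            rng, params.notification_wake_rate_per_hour, params.start_ms, params.end_ms
        )
        dur_ms = max(1000, int(round(params.notification_wake_seconds * 1000)))
        cands.extend((int(t), int(t) + dur_ms, True) for t in notif)
    cands.sort(key=lambda c: c[0])
    return cands


def _thin_overlaps(cands: Sequence[Tuple[int, int, bool]], end_ms: int) -> List[Bout]:
    bouts: List[Bout] = []
    active_end = -1
    for start, end, is_notif in cands:
        if start < active_end or start >= end_ms:
            continue
        end = min(end, end_ms)
        if end <= start:
            continue
        bouts.append(Bout(start, end, notification_filtered_candidate=is_notif))
        active_end = end
    return bouts


def _charge_plan(params: SimParams, rng: np.random.Generator) -> List[Tuple[int, int]]:
    """(plug_ms, unplug_ms) for each night with a charging session."""
    sessions = []
    p_session = min(1.0, params.charge_sessions_per_day)
    for day in range(params.n_days):
        if p_session < 1.0 and rng.uniform() >= p_session:
            continue
        day_start = params.start_ms + day * MS_PER_DAY
        probe = day_start + 12 * MS_PER_HOUR  # mid-day probe picks the active schedule
        s_local, e_local = _sleep_interval(params, probe)
        sleep_minutes = (e_local - s_local) % 1440
        utc_minute = (s_local - params.tz_offset_hours * 60.0) % 1440
        plug = day_start + int(round(utc_minute * MS_PER_MINUTE))
        unplug = plug + int(round(sleep_minutes * MS_PER_MINUTE))
        sessions.append((plug, min(unplug, params.end_ms)))
    return [(p, u) for p, u in sessions if p < params.end_ms]


def _integer_crossings(t1: int, l1: float, t2: int, slope_per_ms: float) -> List[Tuple[int, int]]:
    """Battery events at each integer-percent level crossed on a linear segment.

    The start level itself is not re-emitted; a crossing landing exactly on
    ``t2`` is included.
    """
    events: List[Tuple[int, int]] = []
    l2 = l1 + slope_per_ms * (t2 - t1)
    if slope_per_ms < 0:
        k = math.floor(l1 - 1e-9)
        while k >= l2 - 1e-9 and k >= 0:
            t = t1 + (k - l1) / slope_per_ms
            if t <= t2:
                events.append((int(round(t)), k))
            k -= 1
    elif slope_per_ms > 0:
        k = math.ceil(l1 + 1e-9)
        while k <= l2 + 1e-9 and k <= 100:
            t = t1 + (k - l1) / slope_per_ms
            if t <= t2:
                events.append((int(round(t)), k))
            k += 1
    return events


def _battery_events(params: SimParams, rng: np.random.Generator) -> List[Tuple[int, int]]:
    """Piecewise-linear battery trajectory -> (timestamp, level) events."""
    drain = params.battery_drain_pct_per_hour / MS_PER_HOUR
    charge = params.battery_charge_pct_per_hour / MS_PER_HOUR
    sessions = _charge_plan(params, rng)

    events: List[Tuple[int, int]] = []
    level = float(params.battery_start_pct)
    t = params.start_ms
    events.append((t, int(round(level))))

    def run_drain(t_from: int, t_to: int) -> None:
        nonlocal level, t
        if t_to <= t_from or drain <= 0:
            t = max(t, t_to)
            return
        t_zero = t_from + level / drain
        t_stop = min(t_to, t_zero)
        events.extend(_integer_crossings(t_from, level, int(t_stop), -drain))
        level = max(0.0, level - drain * (t_stop - t_from))
        t = t_to  # flat at 0% emits nothing

    def run_charge(t_from: int, t_to: int) -> None:
        nonlocal level, t
        if t_to <= t_from or charge <= 0:
            t = max(t, t_to)
            return
        t_full = t_from + (100.0 - level) / charge
        t_stop = min(t_to, t_full)
        events.extend(_integer_crossings(t_from, level, int(t_stop), charge))
        level = min(100.0, level + charge * (t_stop - t_from))
        t = t_to  # flat at 100% on the charger emits nothing

    for plug, unplug in sessions:
        run_drain(t, min(plug, params.end_ms))
        if plug >= params.end_ms:
            break
        run_charge(plug, min(unplug, params.end_ms))
    run_drain(t, params.end_ms)
    return [(ts, lv) for ts, lv in events if params.start_ms <= ts < params.end_ms]


def simulate_participant(params: SimParams) -> SimOutput:
    """Simulate one participant's log and its ground truth.

    Deterministic in ``(params, seed)``.  ``truth_valid_days`` holds the
    full-data validity labels: for iOS the battery heuristic applied to the
    pre-dropout stream, for Android the 8-distinct-hour rule applied to the
    non-notification truth bouts — i.e. what a perfect logger would have
    been labeled.
    """
    rng = np.random.default_rng(params.seed)
    cands = _draw_bout_candidates(params, rng)
    truth = _thin_overlaps(cands, params.end_ms)

    open_kind = EventKind.UNLOCKED if params.os is OS.IOS else EventKind.SCREEN_ON
    close_kind = EventKind.LOCKED if params.os is OS.IOS else EventKind.SCREEN_OFF
    records = []
    for b in truth:
        records.append(EventRecord(b.start_ms, params.os, open_kind))
        records.append(EventRecord(b.end_ms, params.os, close_kind))
    if params.os is OS.IOS:
        for ts, lv in _battery_events(params, rng):
            records.append(EventRecord(ts, params.os, EventKind.BATTERY, battery_level=lv))
    stream = EventStream.from_records(params.participant_id, params.os, records)

    span = pd.date_range(
        pd.Timestamp(params.start_ms, unit="ms", tz="UTC"), periods=params.n_days, freq="D"
    )
    if params.os is OS.IOS:
        days = ios_valid_days(ios_valid_minutes(stream))
    else:
        days = android_valid_days([b for b in truth if not b.notification_filtered_candidate])
    truth_valid = days.reindex(span, fill_value=False).astype(bool)
    truth_valid.name = "day_valid"

    out = SimOutput(stream=stream, truth_bouts=tuple(truth), truth_valid_days=truth_valid, params=params)
    if params.dropout_windows:
        out = inject_dropout(out, params.dropout_windows)
    return out


def inject_dropout(output: SimOutput, windows: Sequence[Tuple[int, int]]) -> SimOutput:
    """Delete events inside the given ``[start_ms, end_ms)`` windows.

    Emulates sensor noncollection: the stream loses events but the truth is
    kept unchanged so recovery can be scored against it.
    """
    def dropped(ts: int) -> bool:
        return any(w0 <= ts < w1 for w0, w1 in windows)

    kept = [r for r in output.stream.records if not dropped(r.timestamp_ms)]
    stream = EventStream(output.stream.participant_id, output.stream.os, tuple(kept))
    return replace(output, stream=stream)


def simulate_dst_cohort(
    n_participants: int,
    base: SimParams,
    shift_minutes: float,
    transition_instant: int,
) -> List[SimOutput]:
    """Simulate a cohort whose sleep schedule shifts after a DST transition.

    Per-participant seeds are derived deterministically from ``base.seed``
    via a seed sequence, so two runs with the same master seed produce
    identical streams.
    """
    if n_participants < 2:
        raise ContractViolationError("a cohort needs at least 2 participants")
    child_seeds = np.random.SeedSequence(base.seed).generate_state(n_participants) % (2**31)
    outputs = []
    for i in range(n_participants):
        params = replace(
            base,
            seed=int(child_seeds[i]),
            dst_sleep_shift_minutes=shift_minutes,
            dst_transition_ms=int(transition_instant),
            participant_id=f"sim-{i + 1:03d}",
        )
        outputs.append(simulate_participant(params))
    return outputs
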