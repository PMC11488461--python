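"""Per-minute and per-day data-validity labeling, and the analysis-sample filter.

Passive logging apps silently stop collecting when the host OS suspends
them, so raw logs must be screened for coverage before any screen-time
measure is trusted.  The two operating systems need different heuristics:

* **iOS** emits one battery event per 1% charge change, giving an
  independent heartbeat.  A *valid minute* is one where (criterion 1) the
  battery level was changing at least 1% per hour — operationalized as lying
  in a gap of at most 60 minutes between consecutive battery events — or
  (criterion 2) the phone had recently charged to 100% and sat on the
  charger, for at most 12 hours after the 100% event.  A *valid day* has at
  least 1080 valid minutes (18 hours).
* **Android** has no battery telemetry, so valid minutes cannot be defined;
  a *valid day* is one with screen-on bouts in at least 8 distinct hours.

The analysis sample keeps a valid day only if it belongs to some 28-day
period with at least 14 valid days, and keeps a participant only with at
least 28 such retained days.

Days and minutes are half-open UTC intervals; day series are indexed by
midnight-UTC timestamps.
"""

from __future__ import annotations

from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .errors import UnsupportedOSError
from .state_logs import OS, EventKind, EventStream

__all__ = [
    "ios_valid_minutes",
    "ios_valid_days",
    "android_valid_days",
    "analysis_day_filter",
    "AnalysisSample",
    "VALID_DAY_MINUTES_IOS",
    "VALID_DAY_HOURS_ANDROID",
]

MS_PER_MINUTE = 60_000
MS_PER_HOUR = 3_600_000
MS_PER_DAY = 86_400_000

VALID_DAY_MINUTES_IOS = 1080
VALID_DAY_HOURS_ANDROID = 8
FULL_CHARGE_WINDOW_MS = 12 * MS_PER_HOUR
MAX_BATTERY_GAP_MS = MS_PER_HOUR  # 1% per hour <=> consecutive 1%-events <= 60 min apart


def _minute_index(start_ms: int, end_ms: int) -> pd.DatetimeIndex:
    """Minute grid over full UTC days covering [start_ms, end_ms]."""
    day0 = (start_ms // MS_PER_DAY) * MS_PER_DAY
    day1 = (end_ms // MS_PER_DAY + 1) * MS_PER_DAY
    return pd.date_range(
        pd.Timestamp(day0, unit="ms", tz="UTC"),
        pd.Timestamp(day1, unit="ms", tz="UTC"),
        freq="min",
        inclusive="left",
    )


def ios_valid_minutes(stream: EventStream) -> pd.Series:
    """Label each UTC minute of the monitoring span valid/invalid (iOS only).

    The span covers full days from the first to the last record of the
    stream.  A minute is valid if it satisfies either battery criterion; the
    minute containing a qualifying battery event counts as valid (half-open
    minute convention).  Criterion 2 windows terminate at the first
    subsequent battery event below 100% or after 12 hours, whichever comes
    first; repeated 100% events restart the window.
    """
    if stream.os is not OS.IOS:
        raise UnsupportedOSError("valid minutes are defined only for iOS streams")
    if not stream.records:
        return pd.Series(dtype=bool, index=pd.DatetimeIndex([], tz="UTC"))

    index = _minute_index(stream.records[0].timestamp_ms, stream.records[-1].timestamp_ms)
    base = index[0].value // 10**6 // MS_PER_MINUTE
    n = len(index)
    # Difference-array marking: +1 at range start, -1 past range end.
    marks = np.zeros(n + 1, dtype=np.int64)

    battery = [r for r in stream.records if r.kind is EventKind.BATTERY]
    ts = np.array([r.timestamp_ms for r in battery], dtype=np.int64)
    levels = np.array([r.battery_level for r in battery], dtype=np.int64)

    def mark(first_minute: int, last_minute: int) -> None:
        lo = max(first_minute - base, 0)
        hi = min(last_minute - base, n - 1)
        if lo <= hi:
            marks[lo] += 1
            marks[hi + 1] -= 1

    # Criterion 1: gaps <= 60 min between consecutive battery events.
    for i in range(len(ts) - 1):
        if ts[i + 1] - ts[i] <= MAX_BATTERY_GAP_MS:
            mark(ts[i] // MS_PER_MINUTE, ts[i + 1] // MS_PER_MINUTE)

    # Criterion 2: up to 12 h on the charger after a 100% event; a later
    # sub-100% event means discharging resumed and ends the window.
    for i in range(len(ts)):
        if levels[i] != 100:
            continue
        end = ts[i] + FULL_CHARGE_WINDOW_MS
        for j in range(i + 1, len(ts)):
            if levels[j] < 100:
                end = min(end, ts[j])
                break
            if ts[j] >= end:
                break
        if end > ts[i]:
            mark(ts[i] // MS_PER_MINUTE, (end - 1) // MS_PER_MINUTE)

    valid = np.cumsum(marks[:-1]) > 0
    return pd.Series(valid, index=index, name="minute_valid")


def ios_valid_days(minutes: pd.Series) -> pd.Series:
    """A day is valid iff it has at least 1080 valid minutes (18 hours)."""
    if minutes.empty:
        return pd.Series(dtype=bool, index=pd.DatetimeIndex([], tz="UTC"))
    counts = minutes.groupby(minutes.index.normalize()).sum()
    out = counts >= VALID_DAY_MINUTES_IOS
    out.name = "day_valid"
    return out


def android_valid_days(bouts: Sequence) -> pd.Series:
    """A day is valid iff bouts overlap at least 8 distinct hours of it.

    Hour membership uses interval overlap on the half-open bout
    ``[start, end)``: a bout from 07:30 to 09:30 contributes hours 7, 8
    and 9; a bout spanning an hour (or midnight) boundary counts toward all
    hours it touches.  The returned series covers every day between the
    first and last bout.
    """
    if not bouts:
        return pd.Series(dtype=bool, index=pd.DatetimeIndex([], tz="UTC"))
    hours = set()
    for b in bouts:
        first = b.start_ms // MS_PER_HOUR
        last = (b.end_ms - 1) // MS_PER_HOUR
        hours.update(range(first, last + 1))
    hour_arr = np.array(sorted(hours), dtype=np.int64)
    days = hour_arr // 24
    counts = pd.Series(1, index=days).groupby(level=0).sum()

    day0, day1 = bouts[0].start_ms // MS_PER_DAY, (bouts[-1].end_ms - 1) // MS_PER_DAY
    index = pd.date_range(
        pd.Timestamp(day0 * MS_PER_DAY, unit="ms", tz="UTC"),
        pd.Timestamp(day1 * MS_PER_DAY, unit="ms", tz="UTC"),
        freq="D",
    )
    counts = counts.reindex(index.asi8 // 10**6 // MS_PER_DAY, fill_value=0)
    out = pd.Series(counts.to_numpy() >= VALID_DAY_HOURS_ANDROID, index=index, name="day_valid")
    return out


class AnalysisSample(NamedTuple):
    retained_days: pd.DatetimeIndex
    participant_retained: bool


def analysis_day_filter(
    day_valid: pd.Series,
    window_days: int = 28,
    min_valid_in_window: int = 14,
    min_retained_days: int = 28,
) -> AnalysisSample:
    """Apply the analysis-sample day and participant filter.

    A valid day is retained iff some window of 28 consecutive calendar days
    containing it has at least 14 valid days; windows slide by calendar day
    over the participant's observation span and are clipped at the span
    edges (a span shorter than 28 days is a single clipped window).  The
    participant is retained iff at least 28 days are retained.
    """
    if day_valid.empty:
        return AnalysisSample(pd.DatetimeIndex([], tz="UTC"), False)
    full = day_valid.reindex(
        pd.date_range(day_valid.index.min(), day_valid.index.max(), freq="D"),
        fill_value=False,
    )
    v = full.to_numpy(dtype=bool)
    n = len(v)
    w = min(window_days, n)
    csum = np.concatenate([[0], np.cumsum(v)])
    window_ok = np.zeros(n + 1, dtype=np.int64)
    for s in range(n - w + 1):
        if csum[s + w] - csum[s] >= min_valid_in_window:
            window_ok[s] += 1
            window_ok[s + w] -= 1
    covered = np.cumsum(window_ok[:-1]) > 0
    retained = v & covered
    idx = full.index[retained]
    return AnalysisSample(idx, bool(retained.sum() >= min_retained_days))
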