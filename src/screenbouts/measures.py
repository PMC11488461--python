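"""Daily screen-time measures, minute-level grids, and the DST design.

Four daily metrics summarize how screen time accumulates over a
midnight-to-midnight UTC day: total screen-on time and screen-on bout count
capture the volume of use, while mean screen-on and screen-off bout
durations capture its fragmentation.  Bouts are split at UTC midnight and
fragments are counted per day, which makes the conservation identity exact:
the sum of daily totals equals the total extracted bout duration.

For minute-level analysis each participant-day becomes a 1440-point
function of seconds of screen-on time per minute (half-open minutes), which
binarizes to 1 if any screen-on time was recorded in that minute.  Around a
daylight-saving-time (DST) transition these binary profiles form a
function-on-scalar design — pre vs post indicator on a +/- ``window_days``
window with the internally inconsistent transition day excluded — on which
a naive pointwise empirical log odds ratio serves as a sign-recovery
estimator (full functional-regression inference is out of scope).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .bouts import Bout
from .errors import ContractViolationError

__all__ = [
    "split_at_midnight",
    "daily_measures",
    "minute_grid",
    "cohort_daily_summary",
    "DstDesign",
    "dst_design",
    "pointwise_logodds",
    "logodds_to_or",
]

MS_PER_MINUTE = 60_000
MS_PER_DAY = 86_400_000
MINUTES_PER_DAY = 1440


def _day_ts(day_number: int) -> pd.Timestamp:
    return pd.Timestamp(day_number * MS_PER_DAY, unit="ms", tz="UTC")


def split_at_midnight(bouts: Sequence[Bout]) -> list:
    """Split bouts at UTC midnights so every fragment lies within one date.

    Total duration is conserved exactly; provenance flags are carried onto
    every fragment.
    """
    out = []
    for b in bouts:
        start = b.start_ms
        while start < b.end_ms:
            boundary = (start // MS_PER_DAY + 1) * MS_PER_DAY
            end = min(boundary, b.end_ms)
            out.append(replace(b, start_ms=start, end_ms=end))
            start = end
    return out


def daily_measures(
    bouts: Sequence[Bout],
    day_valid: pd.Series,
    participant_id: str = "",
) -> pd.DataFrame:
    """Compute the four daily screen-time metrics for each valid day.

    Parameters
    ----------
    bouts
        Sorted, non-overlapping bouts already split at UTC midnight
        (a bout crossing midnight raises).
    day_valid
        Boolean series indexed by midnight-UTC timestamps; only valid days
        are emitted (invalid days carry unquantified missingness).

    Returns
    -------
    DataFrame with one row per valid day:

    ``total_on_minutes``
        Sum of fragment durations.
    ``on_bout_count``
        Number of bout fragments starting that day.
    ``mean_on_bout_minutes``
        ``total / count`` (NaN when the day has no bouts).
    ``mean_off_bout_minutes``
        Mean of the interior gaps between consecutive fragments; gaps that
        touch the day boundary are censored intervals and excluded, so days
        with fewer than two fragments have NaN.
    ``log_on_bout_count``
        Natural log of the count; NaN when the count is zero (no +1 offset
        is invented).
    """
    for b in bouts:
        if (b.end_ms - 1) // MS_PER_DAY != b.start_ms // MS_PER_DAY:
            raise ContractViolationError(
                "daily_measures requires bouts split at UTC midnight"
            )
    by_day: dict = {}
    for b in bouts:
        by_day.setdefault(b.start_ms // MS_PER_DAY, []).append(b)

    rows = []
    for day_ts, valid in day_valid.items():
        if not valid:
            continue
        day = day_ts.value // 10**6 // MS_PER_DAY
        frags = sorted(by_day.get(day, []), key=lambda b: b.start_ms)
        count = len(frags)
        total_min = sum(f.duration_ms for f in frags) / MS_PER_MINUTE
        mean_on = total_min / count if count else math.nan
        gaps = [
            (b.start_ms - a.end_ms) / MS_PER_MINUTE
            for a, b in zip(frags, frags[1:])
        ]
        mean_off = float(np.mean(gaps)) if gaps else math.nan
        log_count = math.log(count) if count >= 1 else math.nan
        rows.append(
            {
                "participant_id": participant_id,
                "date": day_ts,
                "total_on_minutes": total_min,
                "on_bout_count": count,
                "mean_on_bout_minutes": mean_on,
                "mean_off_bout_minutes": mean_off,
                "log_on_bout_count": log_count,
            }
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "participant_id",
            "date",
            "total_on_minutes",
            "on_bout_count",
            "mean_on_bout_minutes",
            "mean_off_bout_minutes",
            "log_on_bout_count",
        ],
    )
    if out.empty:
        out = out.astype({"date": "datetime64[ns, UTC]", "on_bout_count": int})
    return out


def minute_grid(
    bouts: Sequence[Bout],
    participant_id: str = "",
    days: Optional[pd.DatetimeIndex] = None,
) -> pd.DataFrame:
    """Screen-on seconds for every minute of every day in the span.

    ``on_seconds`` for minute *m* is the total overlap of bouts with the
    half-open interval ``[m, m + 60 s)``; ``binary_on`` is 1 iff any
    screen-on time was recorded in that minute.  ``days`` defaults to every
    UTC date from the first to the last bout; pass it explicitly to pin the
    grid to a fixed observation window (days without bouts are all-zero).

    Returns a long DataFrame with columns
    ``participant_id, date, minute, on_seconds, binary_on``.
    """
    if days is None:
        if not bouts:
            empty = pd.DataFrame(
                columns=["participant_id", "date", "minute", "on_seconds", "binary_on"]
            )
            return empty.astype(
                {"date": "datetime64[ns, UTC]", "minute": int, "on_seconds": float, "binary_on": np.int8}
            )
        lo = min(b.start_ms for b in bouts) // MS_PER_DAY
        hi = (max(b.end_ms for b in bouts) - 1) // MS_PER_DAY
        days = pd.date_range(_day_ts(lo), _day_ts(hi), freq="D")

    day_numbers = days.asi8 // 10**6 // MS_PER_DAY
    pos = {d: i for i, d in enumerate(day_numbers)}
    seconds = np.zeros((len(days), MINUTES_PER_DAY), dtype=float)

    for b in bouts:
        first = b.start_ms // MS_PER_MINUTE
        last = (b.end_ms - 1) // MS_PER_MINUTE
        for m in range(first, last + 1):
            i = pos.get(m // MINUTES_PER_DAY)
            if i is None:
                continue
            lo_ms = max(b.start_ms, m * MS_PER_MINUTE)
            hi_ms = min(b.end_ms, (m + 1) * MS_PER_MINUTE)
            seconds[i, m % MINUTES_PER_DAY] += (hi_ms - lo_ms) / 1000.0

    out = pd.DataFrame(
        {
            "participant_id": participant_id,
            "date": np.repeat(days, MINUTES_PER_DAY),
            "minute": np.tile(np.arange(MINUTES_PER_DAY), len(days)),
            "on_seconds": seconds.ravel(),
        }
    )
    out["binary_on"] = (out["on_seconds"] > 0).astype(np.int8)
    return out


def cohort_daily_summary(
    measures: pd.DataFrame,
    value: str,
    smooth_days: int = 7,
) -> pd.DataFrame:
    """Cohort percentiles of a daily measure by relative day, 7-day smoothed.

    Days are aligned on each participant's study start (their first emitted
    day).  For each relative day the 10th/25th/50th/75th/90th percentiles of
    ``measures[value]`` across participants are computed, then smoothed with
    a centered moving average (edge days use the available part of the
    window).
    """
    df = measures.copy()
    start = df.groupby("participant_id")["date"].transform("min")
    df["rel_day"] = (df["date"] - start).dt.days
    q = (
        df.groupby("rel_day")[value]
        .quantile([0.10, 0.25, 0.50, 0.75, 0.90])
        .unstack()
    )
    q.columns = ["p10", "p25", "p50", "p75", "p90"]
    q = q.sort_index()
    smoothed = q.rolling(smooth_days, center=True, min_periods=1).mean()
    return smoothed.reset_index()


@dataclass(frozen=True)
class DstDesign:
    """Minute-level binary-use design around one DST transition.

    ``matrix`` is (participant-days x 1440) of 0/1 screen-on indicators;
    ``meta`` has one row per participant-day with ``participant_id``,
    ``date`` and the scalar covariate ``post`` (1 iff the date is after the
    transition).  The transition day itself is excluded as internally
    inconsistent in local time.
    """

    matrix: np.ndarray
    meta: pd.DataFrame
    window_days: int
    transition_instant: int


def dst_design(
    grid: pd.DataFrame,
    transition_instant: int,
    window_days: int = 14,
) -> DstDesign:
    """Restrict a minute grid to +/- ``window_days`` around a DST change.

    ``grid`` is the long-format output of :func:`minute_grid`, possibly
    concatenated over participants.  ``transition_instant`` is the epoch-ms
    instant of the clock change; its UTC date is excluded from both groups.
    """
    if window_days <= 0:
        raise ContractViolationError("window_days must be positive")
    tday = transition_instant // MS_PER_DAY
    day_numbers = grid["date"].values.astype("datetime64[ms]").astype(np.int64) // MS_PER_DAY
    offset = day_numbers - tday
    keep = (np.abs(offset) <= window_days) & (offset != 0)
    sub = grid.loc[keep]

    wide = sub.pivot_table(
        index=["participant_id", "date"], columns="minute", values="binary_on"
    ).reindex(columns=range(MINUTES_PER_DAY), fill_value=0)
    meta = wide.index.to_frame(index=False)
    meta_days = meta["date"].values.astype("datetime64[ms]").astype(np.int64) // MS_PER_DAY
    meta["post"] = (meta_days > tday).astype(np.int8)
    return DstDesign(
        matrix=wide.to_numpy(dtype=np.int8),
        meta=meta,
        window_days=window_days,
        transition_instant=transition_instant,
    )


def pointwise_logodds(design: DstDesign) -> np.ndarray:
    """Naive per-minute empirical log odds ratio of screen use, post vs pre.

    For each of the 1440 minutes the empirical screen-on proportion is
    computed in the pre and post groups and the log odds ratio
    ``log[(p1/(1-p1)) / (p0/(1-p0))]`` is returned, with a 0.5/n continuity
    correction applied when a group proportion is 0 or 1.  This is a
    sign-recovery stand-in for functional mixed-model inference, not an
    inferential estimator: it ignores within-participant correlation.
    """
    post = design.meta["post"].to_numpy(dtype=bool)
    if not post.any() or post.all():
        raise ContractViolationError("both pre and post groups must be non-empty")

    def adjusted_p(rows: np.ndarray) -> np.ndarray:
        n = rows.shape[0]
        p = rows.mean(axis=0)
        return np.clip(p, 0.5 / n, 1.0 - 0.5 / n)

    p0 = adjusted_p(design.matrix[~post])
    p1 = adjusted_p(design.matrix[post])
    return np.log(p1 / (1 - p1)) - np.log(p0 / (1 - p0))


def logodds_to_or(beta: float) -> float:
    """Odds ratio ``exp(beta)`` for reporting a log-odds effect."""
    return math.exp(beta)
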