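"""Screen-on bout extraction from normalized event sequences.

A screen-on bout is a maximal period of consecutive screen use delimited by
open (unlock / screen-on) and close (lock / screen-off) events.  Real logs
drop events, so the default extraction imputes missing closes and caps bout
duration at 30 minutes (about the 97th percentile of observed bouts), and —
for Android only — removes very short bouts attributed to notification
arrivals rather than actual use.  Three comparator modes bracket the
sensitivity of downstream measures to these choices:

======================  ======  ===========  =====================
mode                    impute  cap          intended reading
======================  ======  ===========  =====================
default                 yes     30 min       proposed preprocessing
comparator1             yes     6 h          generous cap
comparator2             no      none         minimal preprocessing
comparator3             no      30 min       cap without imputation
======================  ======  ===========  =====================
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import List, Optional, Sequence, Union

import pandas as pd

from .errors import ContractViolationError
from .state_logs import OS, EventStream, NormalizedEvent, Role, normalize

logger = logging.getLogger(__name__)

__all__ = [
    "Bout",
    "ExtractionConfig",
    "pair_events",
    "filter_notification_bouts",
    "cap_bouts",
    "extract_bouts",
    "bouts_to_frame",
    "frame_to_bouts",
]

MS_PER_MINUTE = 60_000


@dataclass(frozen=True)
class Bout:
    """Half-open interval ``[start_ms, end_ms)`` of consecutive screen use.

    Provenance flags record whether the close was imputed, whether the bout
    was truncated by the duration cap, and (simulator truth only) whether the
    bout is a notification wake rather than actual use.
    """

    start_ms: int
    end_ms: int
    close_imputed: bool = False
    capped: bool = False
    notification_filtered_candidate: bool = False

    def __post_init__(self) -> None:
        if self.end_ms <= self.start_ms:
            raise ContractViolationError("bouts must have end_ms > start_ms")

    @property
    def duration_ms(self) -> int:
        return self.end_ms - self.start_ms

    @property
    def duration_s(self) -> float:
        return self.duration_ms / 1000.0

    @property
    def duration_min(self) -> float:
        return self.duration_ms / MS_PER_MINUTE


@dataclass(frozen=True)
class ExtractionConfig:
    """Bout-extraction settings; use the classmethod constructors for the
    four named modes."""

    impute: bool = True
    cap_minutes: Optional[float] = 30.0
    notification_min_seconds: float = 10.0
    mode_name: str = "default"

    def __post_init__(self) -> None:
        if self.cap_minutes is not None and self.cap_minutes <= 0:
            raise ContractViolationError("cap_minutes must be positive or None")
        if self.notification_min_seconds < 0:
            raise ContractViolationError("notification_min_seconds must be >= 0")

    @classmethod
    def default(cls, **kw) -> "ExtractionConfig":
        return cls(impute=True, cap_minutes=30.0, mode_name="default", **kw)

    @classmethod
    def comparator1(cls, **kw) -> "ExtractionConfig":
        return cls(impute=True, cap_minutes=360.0, mode_name="comparator1", **kw)

    @classmethod
    def comparator2(cls, **kw) -> "ExtractionConfig":
        return cls(impute=False, cap_minutes=None, mode_name="comparator2", **kw)

    @classmethod
    def comparator3(cls, **kw) -> "ExtractionConfig":
        return cls(impute=False, cap_minutes=30.0, mode_name="comparator3", **kw)

    @classmethod
    def from_mode(cls, mode_name: str, **kw) -> "ExtractionConfig":
        try:
            factory = {
                "default": cls.default,
                "comparator1": cls.comparator1,
                "comparator2": cls.comparator2,
                "comparator3": cls.comparator3,
            }[mode_name]
        except KeyError:
            raise ContractViolationError(f"unknown extraction mode {mode_name!r}") from None
        return factory(**kw)


def _screen_events(events: Sequence[NormalizedEvent]) -> List[NormalizedEvent]:
    screen = [e for e in events if e.role is not Role.BATTERY]
    for a, b in zip(screen, screen[1:]):
        if b.timestamp_ms < a.timestamp_ms:
            raise ContractViolationError("events must be time-ordered")
    return screen


def pair_events(
    events: Sequence[NormalizedEvent],
    impute: bool,
    end_cap_minutes: Optional[float] = None,
) -> List[Bout]:
    """Pair open/close events into bouts; battery events are ignored.

    With ``impute=True`` a state machine recovers from missing events: an
    open arriving while a bout is already open closes the current bout at the
    new open's timestamp (``close_imputed``); a close with no open bout is
    dropped (an open time cannot be bounded from the left without inventing
    data); a bout still open at end-of-stream is closed at
    ``start + end_cap_minutes`` when a cap is configured and dropped
    otherwise.  With ``impute=False`` only adjacent (open, close) pairs with
    no intervening screen event form bouts and everything unmatched is
    discarded.

    Zero-length bouts are dropped.  Output is sorted and pairwise
    non-overlapping.
    """
    screen = _screen_events(events)
    bouts: List[Bout] = []

    if impute:
        open_t: Optional[int] = None
        for ev in screen:
            if ev.role is Role.OPEN:
                if open_t is not None and ev.timestamp_ms > open_t:
                    bouts.append(Bout(open_t, ev.timestamp_ms, close_imputed=True))
                open_t = ev.timestamp_ms
            else:  # close
                if open_t is not None:
                    if ev.timestamp_ms > open_t:
                        bouts.append(Bout(open_t, ev.timestamp_ms))
                    open_t = None
        if open_t is not None and end_cap_minutes is not None:
            bouts.append(
                Bout(
                    open_t,
                    open_t + int(round(end_cap_minutes * MS_PER_MINUTE)),
                    close_imputed=True,
                    capped=True,
                )
            )
    else:
        i = 0
        while i + 1 < len(screen):
            a, b = screen[i], screen[i + 1]
            if a.role is Role.OPEN and b.role is Role.CLOSE:
                if b.timestamp_ms > a.timestamp_ms:
                    bouts.append(Bout(a.timestamp_ms, b.timestamp_ms))
                i += 2
            else:
                i += 1
    return bouts


def filter_notification_bouts(
    bouts: Sequence[Bout], min_seconds: float, os: Union[OS, str]
) -> List[Bout]:
    """Drop Android bouts shorter than ``min_seconds`` (notification wakes).

    Android screens wake briefly on notification arrival without any user
    interaction; such sub-threshold bouts are removed.  iOS unlock events
    require interaction, so for iOS this is the identity.  The removed count
    is logged.  ``min_seconds=0`` disables the filter for both systems.
    """
    if min_seconds < 0:
        raise ContractViolationError("min_seconds must be >= 0")
    os = OS(os)
    if os is not OS.ANDROID or min_seconds == 0:
        return list(bouts)
    kept = [b for b in bouts if b.duration_ms >= min_seconds * 1000.0]
    removed = len(bouts) - len(kept)
    if removed:
        logger.info("notification filter removed %d bouts < %.1f s", removed, min_seconds)
    return kept


def cap_bouts(bouts: Sequence[Bout], cap_minutes: Optional[float]) -> List[Bout]:
    """Truncate bouts longer than ``cap_minutes`` (flagging ``capped``).

    Capping bounds the overestimation caused by imputed closes; ``None``
    disables it (identity).
    """
    if cap_minutes is None:
        return list(bouts)
    if cap_minutes <= 0:
        raise ContractViolationError("cap_minutes must be positive")
    cap_ms = int(round(cap_minutes * MS_PER_MINUTE))
    out = []
    for b in bouts:
        if b.duration_ms > cap_ms:
            out.append(replace(b, end_ms=b.start_ms + cap_ms, capped=True))
        else:
            out.append(b)
    return out


def extract_bouts(stream: EventStream, config: ExtractionConfig) -> List[Bout]:
    """Full extraction: normalize -> pair -> notification filter -> cap.

    The notification filter runs before capping: capping cannot create short
    bouts, so the order is safe, and the cap keeps the last word on duration.
    Output is deterministic, sorted, and non-overlapping.
    """
    events = normalize(stream)
    paired = pair_events(
        events,
        impute=config.impute,
        end_cap_minutes=config.cap_minutes if config.impute else None,
    )
    filtered = filter_notification_bouts(paired, config.notification_min_seconds, stream.os)
    return cap_bouts(filtered, config.cap_minutes)


def bouts_to_frame(bouts: Sequence[Bout], participant_id: str = "") -> pd.DataFrame:
    """Tabular form used by the CLI's bout CSVs."""
    return pd.DataFrame(
        {
            "participant_id": participant_id,
            "start_ms": [b.start_ms for b in bouts],
            "end_ms": [b.end_ms for b in bouts],
            "duration_s": [b.duration_s for b in bouts],
            "close_imputed": [b.close_imputed for b in bouts],
            "capped": [b.capped for b in bouts],
        },
        columns=["participant_id", "start_ms", "end_ms", "duration_s", "close_imputed", "capped"],
    )


def frame_to_bouts(frame: pd.DataFrame) -> List[Bout]:
    """Inverse of :func:`bouts_to_frame` (``duration_s`` is derived, ignored)."""
    return [
        Bout(
            start_ms=int(row.start_ms),
            end_ms=int(row.end_ms),
            close_imputed=bool(getattr(row, "close_imputed", False)),
            capped=bool(getattr(row, "capped", False)),
        )
        for row in frame.itertuples(index=False)
    ]
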