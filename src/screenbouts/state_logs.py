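"""Data model and I/O for raw smartphone power-state logs.

The two mobile operating systems report screen state differently: iOS logs
"Unlocked"/"Locked" events plus one battery event for every 1% change in
battery charge level, while Android logs "Screen turned on"/"Screen turned
off" events and no battery telemetry.  Timestamps are epoch milliseconds in
UTC.  This module parses one CSV file per participant into an
:class:`EventStream` and normalizes the two OS vocabularies into a single
open/close/battery role scheme used by every downstream stage.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Optional, Union

import pandas as pd

from .errors import ContractViolationError, EmptyStreamError

logger = logging.getLogger(__name__)

__all__ = [
    "OS",
    "EventKind",
    "Role",
    "EventRecord",
    "EventStream",
    "NormalizedEvent",
    "read_log",
    "write_log",
    "normalize",
    "DEFAULT_COLUMNS",
]


class OS(str, Enum):
    IOS = "ios"
    ANDROID = "android"


class EventKind(str, Enum):
    UNLOCKED = "unlocked"
    LOCKED = "locked"
    SCREEN_ON = "screen_on"
    SCREEN_OFF = "screen_off"
    BATTERY = "battery"


class Role(str, Enum):
    OPEN = "open"
    CLOSE = "close"
    BATTERY = "battery"


#: Logical -> physical column names of the default CSV dialect.  The
#: "UTC time" column is written for human readability but ignored on read;
#: the epoch-millisecond timestamp is the authoritative clock.
DEFAULT_COLUMNS: Mapping[str, str] = {
    "timestamp": "timestamp",
    "utc_time": "UTC time",
    "event": "event",
    "level": "level",
}

# Event-string matching is case-insensitive and whitespace-trimmed: platform
# logs vary in casing ("Screen turned on" vs "screen turned on").
_EVENT_STRINGS: Mapping[str, EventKind] = {
    "unlocked": EventKind.UNLOCKED,
    "locked": EventKind.LOCKED,
    "screen turned on": EventKind.SCREEN_ON,
    "screen turned off": EventKind.SCREEN_OFF,
    "battery": EventKind.BATTERY,
}

_EVENT_LABELS: Mapping[EventKind, str] = {
    EventKind.UNLOCKED: "Unlocked",
    EventKind.LOCKED: "Locked",
    EventKind.SCREEN_ON: "Screen turned on",
    EventKind.SCREEN_OFF: "Screen turned off",
    EventKind.BATTERY: "battery",
}

_KINDS_BY_OS: Mapping[OS, frozenset] = {
    OS.IOS: frozenset({EventKind.UNLOCKED, EventKind.LOCKED, EventKind.BATTERY}),
    OS.ANDROID: frozenset({EventKind.SCREEN_ON, EventKind.SCREEN_OFF}),
}

_ROLE_OF_KIND: Mapping[EventKind, Role] = {
    EventKind.UNLOCKED: Role.OPEN,
    EventKind.SCREEN_ON: Role.OPEN,
    EventKind.LOCKED: Role.CLOSE,
    EventKind.SCREEN_OFF: Role.CLOSE,
    EventKind.BATTERY: Role.BATTERY,
}


@dataclass(frozen=True)
class EventRecord:
    """One raw log row.

    ``battery_level`` is present iff ``kind`` is battery; battery events
    occur only on iOS (one event per 1% change in charge level).
    """

    timestamp_ms: int
    os: OS
    kind: EventKind
    battery_level: Optional[int] = None

    def __post_init__(self) -> None:
        if self.timestamp_ms < 0:
            raise ContractViolationError("timestamp_ms must be non-negative")
        if self.kind not in _KINDS_BY_OS[self.os]:
            raise ContractViolationError(
                f"event kind {self.kind.value!r} is not valid for os={self.os.value!r}"
            )
        if self.kind is EventKind.BATTERY:
            if self.battery_level is None or not 0 <= self.battery_level <= 100:
                raise ContractViolationError(
                    "battery events require battery_level in [0, 100]"
                )
        elif self.battery_level is not None:
            raise ContractViolationError(
                "battery_level is only allowed on battery events"
            )


@dataclass(frozen=True)
class EventStream:
    """A participant's time-ordered power-state log for one OS.

    Records are sorted non-decreasing by timestamp (stable: millisecond ties
    keep file order) and all share the stream's OS.
    """

    participant_id: str
    os: OS
    records: tuple = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "records", tuple(self.records))
        prev = None
        for rec in self.records:
            if rec.os is not self.os:
                raise ContractViolationError(
                    f"record os {rec.os.value!r} differs from stream os {self.os.value!r}"
                )
            if prev is not None and rec.timestamp_ms < prev:
                raise ContractViolationError("records must be time-ordered")
            prev = rec.timestamp_ms

    @classmethod
    def from_records(
        cls, participant_id: str, os: OS, records: Iterable[EventRecord]
    ) -> "EventStream":
        """Build a stream, stably sorting records by timestamp."""
        ordered = sorted(records, key=lambda r: r.timestamp_ms)
        return cls(participant_id=participant_id, os=os, records=tuple(ordered))

    def __len__(self) -> int:
        return len(self.records)

    def to_frame(self) -> pd.DataFrame:
        """Tabular view of the stream (one row per record)."""
        return pd.DataFrame(
            {
                "timestamp_ms": [r.timestamp_ms for r in self.records],
                "event": [r.kind.value for r in self.records],
                "battery_level": [r.battery_level for r in self.records],
            }
        )


@dataclass(frozen=True)
class NormalizedEvent:
    """OS-agnostic event: unlock/screen-on -> open, lock/screen-off -> close."""

    timestamp_ms: int
    role: Role
    battery_level: Optional[int] = None


def _resolve_columns(column_map: Optional[Mapping[str, str]]) -> Mapping[str, str]:
    cols = dict(DEFAULT_COLUMNS)
    if column_map:
        unknown = set(column_map) - set(DEFAULT_COLUMNS)
        if unknown:
            raise ContractViolationError(
                f"unknown logical column names in column_map: {sorted(unknown)}"
            )
        cols.update(column_map)
    return cols


def read_log(
    path: Union[str, Path],
    os: Union[OS, str],
    column_map: Optional[Mapping[str, str]] = None,
    participant_id: Optional[str] = None,
) -> EventStream:
    """Read one participant's power-state CSV into a sorted :class:`EventStream`.

    Rows whose event string is not recognized for the declared OS are skipped
    and counted (logged at WARNING level).  A file with data rows but no
    parseable ones raises :class:`~screenbouts.errors.EmptyStreamError`; a
    header-only file yields an empty stream.

    Parameters
    ----------
    path
        CSV file with columns per :data:`DEFAULT_COLUMNS` or ``column_map``.
    os
        Declared operating system of the device that produced the log.
    column_map
        Optional overrides mapping logical names (``timestamp``, ``event``,
        ``level``) to physical CSV column names.
    participant_id
        Defaults to the file's stem.
    """
    os = OS(os)
    path = Path(path)
    cols = _resolve_columns(column_map)
    pid = participant_id if participant_id is not None else path.stem

    records = []
    n_rows = 0
    n_skipped = 0
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise EmptyStreamError(f"{path}: file has no header row")
        for row in reader:
            n_rows += 1
            rec = _parse_row(row, cols, os)
            if rec is None:
                n_skipped += 1
            else:
                records.append(rec)

    if n_skipped:
        logger.warning("%s: skipped %d of %d rows with unrecognized events", path, n_skipped, n_rows)
    if n_rows > 0 and not records:
        raise EmptyStreamError(f"{path}: {n_rows} rows but none parseable for os={os.value}")
    return EventStream.from_records(pid, os, records)


def _parse_row(row: Mapping[str, str], cols: Mapping[str, str], os: OS) -> Optional[EventRecord]:
    try:
        ts = int(float(row[cols["timestamp"]]))
    except (KeyError, TypeError, ValueError):
        return None
    raw_event = (row.get(cols["event"]) or "").strip().lower()
    raw_level = (row.get(cols["level"]) or "").strip()

    kind = _EVENT_STRINGS.get(raw_event)
    if kind is None and not raw_event and raw_level:
        # Battery rows in some log dialects carry only the level column.
        kind = EventKind.BATTERY
    if kind is None or kind not in _KINDS_BY_OS[os]:
        return None

    level: Optional[int] = None
    if kind is EventKind.BATTERY:
        try:
            level = int(round(float(raw_level)))
        except (TypeError, ValueError):
            return None
        if not 0 <= level <= 100:
            return None
    return EventRecord(timestamp_ms=ts, os=os, kind=kind, battery_level=level)


def write_log(stream: EventStream, path: Union[str, Path]) -> None:
    """Write a stream in the default CSV dialect (round-trips with :func:`read_log`).

    The ``level`` column is populated only on battery rows; ``UTC time`` is a
    derived human-readable rendering of the authoritative epoch timestamp.
    """
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(list(DEFAULT_COLUMNS.values()))
        for rec in stream.records:
            utc = pd.Timestamp(rec.timestamp_ms, unit="ms", tz="UTC").isoformat()
            level = "" if rec.battery_level is None else str(rec.battery_level)
            writer.writerow([rec.timestamp_ms, utc, _EVENT_LABELS[rec.kind], level])


def normalize(stream: EventStream) -> list:
    """Map a stream's records into OS-agnostic :class:`NormalizedEvent` roles.

    Total on valid input: every screen event maps to exactly one of
    open/close, battery events are preserved, order is unchanged.
    """
    return [
        NormalizedEvent(
            timestamp_ms=rec.timestamp_ms,
            role=_ROLE_OF_KIND[rec.kind],
            battery_level=rec.battery_level,
        )
        for rec in stream.records
    ]
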