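from __future__ import annotations

import pytest

from screenbouts.state_logs import (
    OS,
    EventKind,
    EventRecord,
    EventStream,
    NormalizedEvent,
    Role,
)

MS_PER_MINUTE = 60_000
MS_PER_HOUR = 3_600_000
MS_PER_DAY = 86_400_000


def ne(t_ms: int, role: str) -> NormalizedEvent:
    """Shorthand for a normalized event at an epoch-ms timestamp."""
    return NormalizedEvent(timestamp_ms=t_ms, role=Role(role))


def ios_stream(records, pid="p1") -> EventStream:
    return EventStream.from_records(pid, OS.IOS, records)


def battery(t_ms: int, level: int) -> EventRecord:
    return EventRecord(t_ms, OS.IOS, EventKind.BATTERY, battery_level=level)


@pytest.fixture
def write_csv(tmp_path):
    """Write CSV text to a temp file and return its path."""

    def _write(text: str, name: str = "log.csv"):
        path = tmp_path / name
        path.write_text(text, encoding="utf-8")
        return path

    return _write
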