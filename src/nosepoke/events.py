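"""The 1-ms-resolution behavioral event log.

Behavioral hardware registers every state change — an infrared beam break
at the odor port, a valve opening, a TTL edge — as a time-stamped event
with a device location and an analog magnitude.  This module defines that
data model, a plain-text CSV serialization of it, and the pairing of
``on``/``off`` events into investigation bouts (intervals).

The on-disk dialect is UTF-8 CSV with LF line endings:

.. code-block:: text

    # animal: m042
    # assay: cross_habituation
    time_ms,event_type,location,magnitude
    5123,on,odor_port_ir,1
    5410,off,odor_port_ir,1

``#``-prefixed lines before the header carry free-form ``key: value``
metadata.  Timestamps are integer milliseconds from log start; wall-clock
dates belong in the metadata, never in the event stream.
"""

from __future__ import annotations

import csv
import io
import warnings
from dataclasses import dataclass, field

__all__ = [
    "Event",
    "EventInterval",
    "EventLog",
    "PairingResult",
    "parse_event_log",
    "write_event_log",
    "pair_events",
]

_HEADER = ["time_ms", "event_type", "location", "magnitude"]
_EVENT_TYPES = ("on", "off")


@dataclass(frozen=True)
class Event:
    """A single time-stamped state change at a device location."""

    time_ms: int
    event_type: str  # "on" | "off"
    location: str
    magnitude: float = 0.0

    def __post_init__(self):
        if not isinstance(self.time_ms, int) or isinstance(self.time_ms, bool):
            raise ValueError(f"time_ms must be an integer millisecond count, got {self.time_ms!r}")
        if self.time_ms < 0:
            raise ValueError(f"time_ms must be >= 0, got {self.time_ms}")
        if self.event_type not in _EVENT_TYPES:
            raise ValueError(f"event_type must be 'on' or 'off', got {self.event_type!r}")
        if not self.location:
            raise ValueError("location must be a non-empty string")

    @property
    def sort_key(self) -> tuple:
        # off precedes on at identical times so zero-length gaps are representable
        return (self.time_ms, self.location, 0 if self.event_type == "off" else 1)


@dataclass(frozen=True)
class EventInterval:
    """A paired on -> off bout at one location."""

    location: str
    start_ms: int
    end_ms: int

    def __post_init__(self):
        if self.end_ms < self.start_ms:
            raise ValueError(f"end_ms ({self.end_ms}) < start_ms ({self.start_ms})")

    @property
    def duration_ms(self) -> int:
        return self.end_ms - self.start_ms


@dataclass
class EventLog:
    """A time-ordered sequence of events plus free-form header metadata."""

    events: list[Event] = field(default_factory=list)
    meta: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        self.events = sorted(self.events, key=lambda e: e.sort_key)

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)

    @property
    def span_ms(self) -> int:
        """Time of the last event (the log's time extent); 0 for an empty log."""
        return self.events[-1].time_ms if self.events else 0

    def at_location(self, location: str) -> list[Event]:
        return [e for e in self.events if e.location == location]

    def locations(self) -> list[str]:
        return sorted({e.location for e in self.events})


def parse_event_log(stream) -> EventLog:
    """Parse the event-log CSV dialect from a string or text file object.

    ``#``-prefixed lines are metadata (``# key: value``); the first
    non-comment line must be the canonical header.  Malformed rows raise
    :class:`~nosepoke.errors.EventLogParseError` naming the line number.
    """
    from .errors import EventLogParseError

    if isinstance(stream, str):
        stream = io.StringIO(stream)

    meta: dict[str, str] = {}
    events: list[Event] = []
    header_seen = False
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\r\n")
        if not line.strip():
            continue
        if line.lstrip().startswith("#"):
            body = line.lstrip()[1:].strip()
            if ":" in body:
                key, _, value = body.partition(":")
                meta[key.strip()] = value.strip()
            continue
        fields = next(csv.reader([line]))
        if not header_seen:
            if [f.strip() for f in fields] != _HEADER:
                raise EventLogParseError(
                    f"expected header {','.join(_HEADER)!r}, got {line!r}", lineno
                )
            header_seen = True
            continue
        if len(fields) != 4:
            raise EventLogParseError(
                f"expected 4 comma-separated fields, got {len(fields)}", lineno
            )
        t_raw, etype, location, mag_raw = (f.strip() for f in fields)
        try:
            time_ms = int(t_raw)
        except ValueError:
            raise EventLogParseError(
                f"time_ms must be an integer millisecond count, got {t_raw!r}", lineno
            ) from None
        try:
            magnitude = float(mag_raw)
        except ValueError:
            raise EventLogParseError(f"magnitude is not a number: {mag_raw!r}", lineno) from None
        try:
            events.append(Event(time_ms, etype, location, magnitude))
        except ValueError as exc:
            raise EventLogParseError(str(exc), lineno) from None
    if not header_seen:
        raise EventLogParseError(f"missing header line {','.join(_HEADER)!r}")
    return EventLog(events=events, meta=meta)


def write_event_log(log: EventLog) -> str:
    """Serialize a log to the CSV dialect (inverse of :func:`parse_event_log`)."""
    out = io.StringIO()
    for key, value in log.meta.items():
        out.write(f"# {key}: {value}\n")
    out.write(",".join(_HEADER) + "\n")
    for e in log.events:
        out.write(f"{e.time_ms},{e.event_type},{e.location},{e.magnitude:.6g}\n")
    return out.getvalue()


@dataclass
class PairingResult:
    """Intervals produced by on/off pairing plus counts of discarded events."""

    intervals: list[EventInterval]
    n_discarded_on: int = 0
    n_discarded_off: int = 0

    @property
    def n_discarded(self) -> int:
        return self.n_discarded_on + self.n_discarded_off

    def __iter__(self):
        return iter(self.intervals)

    def __len__(self) -> int:
        return len(self.intervals)


def pair_events(log: EventLog, location: str) -> PairingResult:
    """Pair on/off events at ``location`` into investigation bouts.

    Each ``on`` is matched to the next ``off`` at the same location.  A
    second ``on`` while already on is a hardware glitch (the IR beam cannot
    re-break while broken) and is discarded; an ``off`` with no open ``on``
    is discarded; a trailing unmatched ``on`` is closed at the last event
    time of the whole log (the animal was still in the port when recording
    stopped).  Discards are counted and reported via ``warnings.warn``.
    """
    intervals: list[EventInterval] = []
    open_start: int | None = None
    n_disc_on = n_disc_off = 0
    for e in log.at_location(location):
        if e.event_type == "on":
            if open_start is None:
                open_start = e.time_ms
            else:
                n_disc_on += 1
        else:
            if open_start is not None:
                intervals.append(EventInterval(location, open_start, e.time_ms))
                open_start = None
            else:
                n_disc_off += 1
    if open_start is not None:
        intervals.append(EventInterval(location, open_start, max(log.span_ms, open_start)))
    if n_disc_on or n_disc_off:
        warnings.warn(
            f"pair_events({location!r}): discarded {n_disc_on} duplicate 'on' and "
            f"{n_disc_off} unmatched 'off' events",
            stacklevel=2,
        )
    return PairingResult(intervals, n_disc_on, n_disc_off)
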