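"""Raw binary-sensor event streams, the sensor registry and annotations.

An event stream is a plain text file with one record per line —
``timestamp, sensor id, sensor state, inhabitant`` — comma- or
tab-delimited (auto-detected).  Timestamps are ISO-8601, with a
``DD/MM/YYYY HH:MM:SS`` fallback.  Everything is UTF-8.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from datetime import datetime
from pathlib import Path
from typing import Iterable, Iterator, Sequence, Union

import pandas as pd

from .catalogs import SENSOR_TABLE, SENSOR_TYPES
from .errors import FormatError, ValidationError

Source = Union[str, Path, io.TextIOBase]

_TIMESTAMP_FALLBACKS = ("%d/%m/%Y %H:%M:%S", "%d/%m/%Y %H:%M")


@dataclass(frozen=True)
class SensorEvent:
    """One timestamped state change of a binary sensor."""

    timestamp: datetime
    sensor_id: str
    state: str
    inhabitant: str = "Resident"


@dataclass(frozen=True)
class ActivityAnnotation:
    """A labelled ground-truth interval: ``class_id`` active on [start, end)."""

    class_id: str
    start: datetime
    end: datetime

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValidationError(
                f"annotation for {self.class_id}: start {self.start} not before end {self.end}"
            )

    @property
    def duration_seconds(self) -> float:
        return (self.end - self.start).total_seconds()


class SensorRegistry:
    """Catalog of binary sensors: id, object label, type and state pair."""

    def __init__(self, entries: Iterable[tuple[str, str, str, tuple[str, str]]]):
        self._entries: dict[str, tuple[str, str, tuple[str, str]]] = {}
        for sensor_id, obj, stype, states in entries:
            if sensor_id in self._entries:
                raise FormatError(f"duplicate sensor id {sensor_id!r} in registry")
            if stype not in SENSOR_TYPES:
                raise FormatError(
                    f"sensor {sensor_id!r} has unknown type {stype!r}; expected one of {SENSOR_TYPES}"
                )
            states = tuple(states)
            if len(states) != 2:
                raise FormatError(f"sensor {sensor_id!r} must have exactly 2 states, got {states!r}")
            self._entries[sensor_id] = (obj, stype, states)

    # -- container protocol -------------------------------------------------

    def __len__(self) -> int:
        return len(self._entries)

    def __contains__(self, sensor_id: str) -> bool:
        return sensor_id in self._entries

    def __iter__(self) -> Iterator[str]:
        return iter(self._entries)

    @property
    def sensor_ids(self) -> list[str]:
        """Sensor ids in registry order (defines the feature-vector layout)."""
        return list(self._entries)

    # -- lookups ------------------------------------------------------------

    def object_of(self, sensor_id: str) -> str:
        return self._entries[sensor_id][0]

    def type_of(self, sensor_id: str) -> str:
        return self._entries[sensor_id][1]

    def states_of(self, sensor_id: str) -> tuple[str, str]:
        return self._entries[sensor_id][2]

    def active_state_of(self, sensor_id: str) -> str:
        """The 'triggered' state (first of the registered pair)."""
        return self._entries[sensor_id][2][0]

    def validate_event(self, event: SensorEvent) -> None:
        if event.sensor_id not in self._entries:
            raise ValidationError(f"unknown sensor id {event.sensor_id!r}")
        if event.state not in self._entries[event.sensor_id][2]:
            raise ValidationError(
                f"state {event.state!r} not registered for sensor {event.sensor_id!r} "
                f"(expected one of {self._entries[event.sensor_id][2]})"
            )

    # -- construction / persistence ----------------------------------------

    @classmethod
    def default(cls) -> "SensorRegistry":
        """The bundled 30-sensor smart-lab registry."""
        return cls(SENSOR_TABLE)

    @classmethod
    def from_csv(cls, source: Source) -> "SensorRegistry":
        try:
            frame = pd.read_csv(source, dtype=str)
        except Exception as exc:  # pragma: no cover - pandas error text varies
            raise FormatError(f"cannot parse registry table: {exc}") from exc
        required = {"id", "object", "type", "states"}
        missing = required - set(frame.columns)
        if missing:
            raise FormatError(f"registry table missing columns: {sorted(missing)}")
        entries = []
        for row in frame.itertuples(index=False):
            states = tuple(s.strip() for s in str(row.states).split("/"))
            entries.append((row.id, row.object, row.type, states))
        return cls(entries)

    def to_csv(self, path: Union[str, Path]) -> None:
        frame = pd.DataFrame(
            [
                (sid, obj, stype, "/".join(states))
                for sid, (obj, stype, states) in self._entries.items()
            ],
            columns=["id", "object", "type", "states"],
        )
        frame.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Event stream I/O
# ---------------------------------------------------------------------------


def _parse_timestamp(text: str, line_no: int) -> datetime:
    text = text.strip()
    try:
        return datetime.fromisoformat(text)
    except ValueError:
        pass
    for fmt in _TIMESTAMP_FALLBACKS:
        try:
            return datetime.strptime(text, fmt)
        except ValueError:
            continue
    raise FormatError(f"line {line_no}: unparseable timestamp {text!r}")


def _iter_lines(source: Source) -> Iterator[str]:
    if isinstance(source, (str, Path)) and "\n" not in str(source):
        with open(source, "r", encoding="utf-8") as handle:
            yield from handle
    elif isinstance(source, str):
        yield from io.StringIO(source)
    else:
        yield from source


def read_event_stream(source: Source, registry: SensorRegistry) -> list[SensorEvent]:
    """Read a raw event file, validate against ``registry`` and sort by time.

    The delimiter (comma or tab) is auto-detected per line; sorting is
    stable, so simultaneous events keep their input order.
    """
    events: list[tuple[datetime, int, SensorEvent]] = []
    for line_no, line in enumerate(_iter_lines(source), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        delim = "\t" if "\t" in line else ","
        fields = [f.strip() for f in line.split(delim)]
        if len(fields) != 4:
            raise FormatError(
                f"line {line_no}: expected 4 fields (timestamp, sensor, state, inhabitant), "
                f"got {len(fields)}"
            )
        timestamp = _parse_timestamp(fields[0], line_no)
        event = SensorEvent(timestamp, fields[1], fields[2], fields[3])
        registry.validate_event(event)
        events.append((timestamp, line_no, event))
    events.sort(key=lambda item: (item[0], item[1]))
    return [event for _, _, event in events]


def write_event_stream(events: Sequence[SensorEvent], path: Union[str, Path]) -> None:
    """Write events in the raw dialect (comma-delimited, ISO timestamps)."""
    with open(path, "w", encoding="utf-8") as handle:
        for event in events:
            handle.write(
                f"{event.timestamp.isoformat(sep=' ')},{event.sensor_id},"
                f"{event.state},{event.inhabitant}\n"
            )


# ---------------------------------------------------------------------------
# Annotation I/O (CSV of class_id, start, end)
# ---------------------------------------------------------------------------


def read_annotations(source: Source) -> list[ActivityAnnotation]:
    frame = pd.read_csv(source, dtype=str)
    required = {"class_id", "start", "end"}
    missing = required - set(frame.columns)
    if missing:
        raise FormatError(f"annotation table missing columns: {sorted(missing)}")
    annotations = [
        ActivityAnnotation(
            row.class_id,
            datetime.fromisoformat(row.start),
            datetime.fromisoformat(row.end),
        )
        for row in frame.itertuples(index=False)
    ]
    annotations.sort(key=lambda a: a.start)
    return annotations


def write_annotations(annotations: Sequence[ActivityAnnotation], path: Union[str, Path]) -> None:
    frame = pd.DataFrame(
        [(a.class_id, a.start.isoformat(sep=" "), a.end.isoformat(sep=" ")) for a in annotations],
        columns=["class_id", "start", "end"],
    )
    frame.to_csv(path, index=False)
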