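"""Time-window segmentation, feature extraction and window labelling.

Event streams are cut into fixed-length non-overlapping windows (30 s by
default).  Each window becomes one instance: 30 per-sensor features in
registry order plus a scalar time-routine feature, all in [0, 1].
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from datetime import datetime, time, timedelta
from pathlib import Path
from typing import Sequence, Union

import numpy as np
import pandas as pd

from .errors import ValidationError
from .events import ActivityAnnotation, SensorEvent, SensorRegistry

ROUTINE_FEATURE = "routine"


class RoutineTag(enum.Enum):
    """Coarse time-of-day partition used both as a feature and to group models."""

    MORNING = "M"
    AFTERNOON = "A"
    EVENING = "E"

    @property
    def encoded(self) -> float:
        return {"M": 0.0, "A": 0.5, "E": 1.0}[self.value]


#: Routine bins: Morning [06:00, 12:00), Afternoon [12:00, 18:00),
#: Evening [18:00, 06:00) — night hours fold into Evening.
_MORNING_START = time(6, 0)
_AFTERNOON_START = time(12, 0)
_EVENING_START = time(18, 0)


def routine_of(t: datetime) -> RoutineTag:
    """Map a timestamp to its time routine (total over the day)."""
    tod = t.time()
    if _MORNING_START <= tod < _AFTERNOON_START:
        return RoutineTag.MORNING
    if _AFTERNOON_START <= tod < _EVENING_START:
        return RoutineTag.AFTERNOON
    return RoutineTag.EVENING


@dataclass
class Window:
    """A half-open time slice [start, end) with its contained events."""

    start: datetime
    end: datetime
    events: list[SensorEvent] = field(default_factory=list)

    @property
    def routine(self) -> RoutineTag:
        return routine_of(self.start)

    @property
    def midpoint(self) -> datetime:
        return self.start + (self.end - self.start) / 2


@dataclass
class LabeledDataset:
    """Feature matrix ``X`` (N x d) with class labels ``y`` (length N)."""

    X: np.ndarray
    y: np.ndarray
    feature_names: list[str]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=object)
        if self.X.ndim != 2 or len(self.X) != len(self.y):
            raise ValidationError("X and y sizes disagree")
        if self.X.shape[1] != len(self.feature_names):
            raise ValidationError("feature_names length disagrees with X width")

    def __len__(self) -> int:
        return len(self.y)

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def class_counts(self) -> dict[str, int]:
        labels, counts = np.unique(self.y.astype(str), return_counts=True)
        return dict(zip(labels.tolist(), counts.tolist()))

    def subset(self, indices: Sequence[int]) -> "LabeledDataset":
        idx = np.asarray(indices, dtype=int)
        return LabeledDataset(self.X[idx], self.y[idx], list(self.feature_names))

    def relabel(self, mapping: dict[str, str]) -> "LabeledDataset":
        """Return a copy with labels rewritten through ``mapping`` (identity otherwise)."""
        y = np.array([mapping.get(str(label), str(label)) for label in self.y], dtype=object)
        return LabeledDataset(self.X.copy(), y, list(self.feature_names))

    @staticmethod
    def concatenate(parts: Sequence["LabeledDataset"]) -> "LabeledDataset":
        if not parts:
            raise ValidationError("cannot concatenate zero datasets")
        names = parts[0].feature_names
        for part in parts[1:]:
            if part.feature_names != names:
                raise ValidationError("feature name mismatch in concatenate")
        return LabeledDataset(
            np.vstack([p.X for p in parts]),
            np.concatenate([p.y for p in parts]),
            list(names),
        )

    def to_csv(self, path: Union[str, Path]) -> None:
        frame = pd.DataFrame(self.X, columns=self.feature_names)
        frame["label"] = self.y
        frame.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, source: Union[str, Path]) -> "LabeledDataset":
        frame = pd.read_csv(source)
        y = frame.pop("label").to_numpy(dtype=object)
        return cls(frame.to_numpy(dtype=float), y, list(frame.columns))


# ---------------------------------------------------------------------------
# Segmentation
# ---------------------------------------------------------------------------


def segment(
    events: Sequence[SensorEvent],
    window_seconds: float = 30.0,
    origin: datetime | None = None,
) -> list[Window]:
    """Tile ``[origin, last event]`` with half-open fixed-length windows.

    Every event lands in exactly one window (``start <= t < end``).  The
    default origin is midnight of the first event's day, so tilings are
    reproducible regardless of when the first event fired.
    """
    if window_seconds <= 0:
        raise ValidationError("window_seconds must be positive")
    if not events:
        return []
    if origin is None:
        origin = datetime.combine(events[0].timestamp.date(), time.min)
    first, last = events[0].timestamp, events[-1].timestamp
    if first < origin:
        raise ValidationError("origin must not be after the first event")
    step = timedelta(seconds=window_seconds)
    n_windows = int((last - origin) / step) + 1
    windows = [Window(origin + i * step, origin + (i + 1) * step) for i in range(n_windows)]
    for event in events:
        index = int((event.timestamp - origin) / step)
        windows[index].events.append(event)
    return windows


# ---------------------------------------------------------------------------
# Feature extraction
# ---------------------------------------------------------------------------


def extract_features(
    window: Window,
    registry: SensorRegistry,
    mode: str = "indicator",
) -> np.ndarray:
    """One feature per sensor (registry order) plus the routine code.

    ``indicator`` mode sets a sensor's component to 1 if it emitted at least
    one event inside the window.  ``fraction`` mode instead reports the
    fraction of the window spent in the sensor's active state, tracking
    state transitions from the events inside the window (state before the
    first event is taken as inactive).
    """
    if mode not in ("indicator", "fraction"):
        raise ValidationError(f"unknown feature mode {mode!r}")
    order = {sid: k for k, sid in enumerate(registry.sensor_ids)}
    values = np.zeros(len(order) + 1)
    if mode == "indicator":
        for event in window.events:
            values[order[event.sensor_id]] = 1.0
    else:
        span = (window.end - window.start).total_seconds()
        per_sensor: dict[str, list[SensorEvent]] = {}
        for event in window.events:
            per_sensor.setdefault(event.sensor_id, []).append(event)
        for sensor_id, sensor_events in per_sensor.items():
            sensor_events.sort(key=lambda e: e.timestamp)
            active_state = registry.active_state_of(sensor_id)
            active_time = 0.0
            current: datetime | None = None  # start of the open active stretch
            for event in sensor_events:
                if event.state == active_state:
                    if current is None:
                        current = event.timestamp
                elif current is not None:
                    active_time += (event.timestamp - current).total_seconds()
                    current = None
            if current is not None:
                active_time += (window.end - current).total_seconds()
            values[order[sensor_id]] = min(active_time / span, 1.0)
    values[-1] = window.routine.encoded
    return values


def feature_names(registry: SensorRegistry) -> list[str]:
    return registry.sensor_ids + [ROUTINE_FEATURE]


# ---------------------------------------------------------------------------
# Labelling
# ---------------------------------------------------------------------------


def _overlap_seconds(window: Window, annotation: ActivityAnnotation) -> float:
    lo = max(window.start, annotation.start)
    hi = min(window.end, annotation.end)
    return max((hi - lo).total_seconds(), 0.0)


def label_windows(
    windows: Sequence[Window],
    annotations: Sequence[ActivityAnnotation],
    registry: SensorRegistry,
    mode: str = "indicator",
) -> tuple[LabeledDataset, list[Window]]:
    """Assign each window the class of its maximal-overlap annotation.

    Windows overlapping no annotation are discarded and returned separately.
    Overlap ties break toward the earlier-starting annotation.
    """
    ordered = sorted(annotations, key=lambda a: (a.start, a.end))
    rows, labels, discarded = [], [], []
    for window in windows:
        best_class, best_overlap = None, 0.0
        for annotation in ordered:
            if annotation.start >= window.end:
                break
            overlap = _overlap_seconds(window, annotation)
            if overlap > best_overlap:  # strict ">" keeps the earlier start on ties
                best_class, best_overlap = annotation.class_id, overlap
        if best_class is None:
            discarded.append(window)
        else:
            rows.append(extract_features(window, registry, mode))
            labels.append(best_class)
    if rows:
        dataset = LabeledDataset(np.array(rows), np.array(labels, dtype=object), feature_names(registry))
    else:
        dataset = LabeledDataset(
            np.empty((0, len(registry) + 1)), np.empty(0, dtype=object), feature_names(registry)
        )
    return dataset, discarded


def build_dataset(
    events: Sequence[SensorEvent],
    annotations: Sequence[ActivityAnnotation],
    registry: SensorRegistry,
    window_seconds: float = 30.0,
    mode: str = "indicator",
) -> LabeledDataset:
    """Segment, featurize and label an event stream in one call."""
    windows = segment(events, window_seconds)
    dataset, _ = label_windows(windows, annotations, registry, mode)
    return dataset
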