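"""Synthetic single-inhabitant smart-home simulator.

Generates labelled binary-sensor event streams with the statistical
structure the ensemble assumes: activities scheduled inside their time
routines, per-class sensor signatures with a controllable degree of
sharing (interclass similarity), class imbalance, and missing/spurious
firing noise.  Every run is deterministic for a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from datetime import date, datetime, time, timedelta

import numpy as np

from .catalogs import RESTRUCTURED_ROUTINES
from .errors import ValidationError
from .events import ActivityAnnotation, SensorEvent, SensorRegistry

_ROUTINE_BINS = {  # scheduling happens inside [06:00, 24:00)
    "M": (time(6, 0), time(12, 0)),
    "A": (time(12, 0), time(18, 0)),
    "E": (time(18, 0), time(23, 59, 59)),
}

#: Sensors reserved as shared "similarity" targets; primaries and
#: secondaries are drawn from the rest of the registry so that signatures
#: are fully disjoint at overlap amount 0.
_SHARED_TARGETS = {
    "bed": ["C14"],
    "kitchen": ["SM1"],
    "door": ["M01"],
    "sofa": ["S09"],
}

_GROUPS = {
    "bed": ("Act23", "Act24"),
    "kitchen": ("ActN3", "ActN4", "ActN5"),
}

#: Class weights echoing the bundled restructured catalog's imbalance,
#: floored at 60 so even minority classes yield enough windows to split.
_PAPERLIKE_WEIGHTS = {
    "Act01": 60, "Act15": 75, "Act17": 132, "Act18": 60, "Act22": 86,
    "Act23": 60, "Act24": 60, "ActN1": 61, "ActN2": 155, "ActN3": 141,
    "ActN4": 219, "ActN5": 162,
}


@dataclass(frozen=True)
class ActivityTemplate:
    """Generative description of one activity class."""

    class_id: str
    routines: tuple[str, ...]
    duration_median_s: float
    duration_sigma: float
    signature: dict[str, float]  # sensor id -> firing probability per window
    shared_group: str | None = None

    def __post_init__(self) -> None:
        if not self.routines:
            raise ValidationError(f"template {self.class_id}: empty routine set")
        for sensor, probability in self.signature.items():
            if not 0.0 <= probability <= 1.0:
                raise ValidationError(
                    f"template {self.class_id}: probability {probability} for {sensor} outside [0,1]"
                )


@dataclass(frozen=True)
class SimulationConfig:
    templates: tuple[ActivityTemplate, ...]
    days: int = 3
    weights: dict[str, float] = field(default_factory=dict)
    miss_rate: float = 0.0
    spurious_rate: float = 0.0
    seed: int = 0
    start_date: date = date(2021, 3, 1)
    idle_mean_s: float = 2700.0
    inhabitant: str = "Resident"
    #: Schedule every weighted class at least once per day (keeps minority
    #: classes represented); disable for purely weight-proportional draws.
    daily_guarantee: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.miss_rate <= 1.0:
            raise ValidationError("miss_rate must lie in [0,1]")
        if self.spurious_rate < 0:
            raise ValidationError("spurious_rate must be non-negative")
        if any(w < 0 for w in self.weights.values()):
            raise ValidationError("class weights must be non-negative")

    @property
    def catalog(self) -> dict[str, tuple[str, ...]]:
        """Class id -> routine tags, as consumed by build_model_specs."""
        return {t.class_id: t.routines for t in self.templates}


# ---------------------------------------------------------------------------
# Default configurations
# ---------------------------------------------------------------------------


def _assign_sensors(class_ids: list[str]) -> dict[str, tuple[str, str]]:
    """Deterministically give each class a unique (primary, secondary) pair."""
    registry = SensorRegistry.default()
    reserved = {s for sensors in _SHARED_TARGETS.values() for s in sensors}
    pool = [s for s in registry.sensor_ids if s not in reserved]
    if len(pool) < 2 * len(class_ids):
        raise ValidationError("not enough sensors for disjoint signatures")
    return {
        class_id: (pool[2 * k], pool[2 * k + 1]) for k, class_id in enumerate(class_ids)
    }


def _group_of(class_id: str) -> str | None:
    for group, members in _GROUPS.items():
        if class_id in members:
            return group
    return None


def default_config(scale: str = "small", seed: int = 0) -> SimulationConfig:
    """Ready-made configurations.

    ``paper_like`` has the full 12-class routine-tagged catalog with its
    imbalance ratios; ``small`` is a 4-class setup (one class per base
    model) sized for fast tests.
    """
    if scale == "paper_like":
        class_ids = list(RESTRUCTURED_ROUTINES)
        pairs = _assign_sensors(class_ids)
        templates = tuple(
            ActivityTemplate(
                class_id=class_id,
                routines=RESTRUCTURED_ROUTINES[class_id],
                duration_median_s=300.0,
                duration_sigma=0.4,
                signature={pairs[class_id][0]: 1.0, pairs[class_id][1]: 0.5},
                shared_group=_group_of(class_id),
            )
            for class_id in class_ids
        )
        return SimulationConfig(
            templates=templates,
            days=6,
            weights={k: float(v) for k, v in _PAPERLIKE_WEIGHTS.items()},
            seed=seed,
            idle_mean_s=2700.0,
        )
    if scale == "small":
        spec = [
            ("ActS1", ("M",)),
            ("ActS2", ("A",)),
            ("ActS3", ("E",)),
            ("ActS4", ("M", "A", "E")),
        ]
        pairs = _assign_sensors([class_id for class_id, _ in spec])
        templates = tuple(
            ActivityTemplate(
                class_id=class_id,
                routines=routines,
                duration_median_s=180.0,
                duration_sigma=0.3,
                signature={pairs[class_id][0]: 1.0, pairs[class_id][1]: 0.5},
            )
            for class_id, routines in spec
        )
        return SimulationConfig(
            templates=templates,
            days=2,
            weights={class_id: 1.0 for class_id, _ in spec},
            seed=seed,
            idle_mean_s=1200.0,
        )
    raise ValidationError(f"unknown scale {scale!r}; expected 'small' or 'paper_like'")


def overlap_knob(config: SimulationConfig, amount: float) -> SimulationConfig:
    """Move ``amount`` of each grouped template's signature mass onto its
    group's shared sensors.  0 keeps signatures disjoint; 1 makes grouped
    templates fire only their shared sensors.
    """
    if not 0.0 <= amount <= 1.0:
        raise ValidationError("overlap amount must lie in [0,1]")
    new_templates = []
    for template in config.templates:
        if template.shared_group is None or amount == 0.0:
            new_templates.append(template)
            continue
        shared = _SHARED_TARGETS[template.shared_group]
        moved = sum(template.signature.values()) * amount / len(shared)
        signature = {s: p * (1.0 - amount) for s, p in template.signature.items() if p * (1.0 - amount) > 0}
        for sensor in shared:
            signature[sensor] = min(1.0, signature.get(sensor, 0.0) + moved)
        new_templates.append(replace(template, signature=signature))
    return replace(config, templates=tuple(new_templates))


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------


def _window_grid(start: datetime, end: datetime, step_s: float = 30.0):
    """Midnight-aligned 30-s tiles intersecting [start, end)."""
    day_origin = datetime.combine(start.date(), time.min)
    step = timedelta(seconds=step_s)
    k = int((start - day_origin) / step)
    t = day_origin + k * step
    while t < end:
        yield max(t, start), min(t + step, end)
        t += step


def generate(config: SimulationConfig) -> tuple[list[SensorEvent], list[ActivityAnnotation]]:
    """Simulate ``config.days`` days of routine-scheduled activities."""
    rng = np.random.default_rng(config.seed)
    registry = SensorRegistry.default()
    events: list[SensorEvent] = []
    annotations: list[ActivityAnnotation] = []

    by_routine: dict[str, list[ActivityTemplate]] = {r: [] for r in _ROUTINE_BINS}
    for template in config.templates:
        for routine in template.routines:
            by_routine[routine].append(template)

    for day in range(config.days):
        current_date = config.start_date + timedelta(days=day)
        # Daily routine guarantee: every class occurs at least once per day,
        # in a randomly chosen allowed routine; weighted picks fill the rest.
        mandatory: dict[str, list[ActivityTemplate]] = {r: [] for r in _ROUTINE_BINS}
        for template in config.templates:
            if config.daily_guarantee and config.weights.get(template.class_id, 1.0) > 0:
                routine = template.routines[int(rng.integers(len(template.routines)))]
                mandatory[routine].append(template)
        for queue in mandatory.values():
            rng.shuffle(queue)  # type: ignore[arg-type]

        for routine, (bin_start, bin_end) in _ROUTINE_BINS.items():
            candidates = by_routine[routine]
            if not candidates:
                continue
            weights = np.array(
                [config.weights.get(t.class_id, 1.0) for t in candidates], dtype=float
            )
            if weights.sum() == 0:
                continue
            weights /= weights.sum()
            queue = mandatory[routine]
            t = datetime.combine(current_date, bin_start)
            end = datetime.combine(current_date, bin_end)
            while True:
                t = t + timedelta(seconds=float(rng.exponential(config.idle_mean_s)))
                if queue:
                    template = queue.pop()
                else:
                    template = candidates[int(rng.choice(len(candidates), p=weights))]
                duration = float(
                    rng.lognormal(math.log(template.duration_median_s), template.duration_sigma)
                )
                duration = max(duration, 30.0)
                if t + timedelta(seconds=duration) > end:
                    break
                stop = t + timedelta(seconds=duration)
                annotations.append(ActivityAnnotation(template.class_id, t, stop))
                for seg_start, seg_end in _window_grid(t, stop):
                    span = (seg_end - seg_start).total_seconds()
                    for sensor, probability in template.signature.items():
                        if rng.random() >= probability * span / 30.0:
                            continue
                        if config.miss_rate > 0 and rng.random() < config.miss_rate:
                            continue
                        offset = timedelta(seconds=float(rng.uniform(0.0, span)))
                        events.append(
                            SensorEvent(
                                seg_start + offset,
                                sensor,
                                registry.active_state_of(sensor),
                                config.inhabitant,
                            )
                        )
                t = stop

        if config.spurious_rate > 0:
            day_start = datetime.combine(current_date, _ROUTINE_BINS["M"][0])
            day_end = datetime.combine(current_date, _ROUTINE_BINS["E"][1])
            n_windows = int((day_end - day_start).total_seconds() // 30)
            sensor_ids = registry.sensor_ids
            for w in range(n_windows):
                for _ in range(int(rng.poisson(config.spurious_rate))):
                    stamp = day_start + timedelta(seconds=30.0 * w + float(rng.uniform(0, 30)))
                    sensor = sensor_ids[int(rng.integers(len(sensor_ids)))]
                    events.append(
                        SensorEvent(
                            stamp, sensor, registry.active_state_of(sensor), config.inhabitant
                        )
                    )

    events.sort(key=lambda e: e.timestamp)
    annotations.sort(key=lambda a: a.start)
    return events, annotations
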