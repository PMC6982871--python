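"""Base-model class partitions and complement-class data allocation.

The catalog splits into four base models by time routine: classes tagged
with exactly one routine go to that routine's model (Morning, Afternoon,
Evening); everything else goes to the Mixed model.  Each model additionally
trains on a single catch-all *complement* class sampled from the other
models' main classes, under one of two allocation schemes:

* ``model_level`` — the complement budget (the mean main-class training
  count, floored) is shared equally across donor models, then equally
  across each donor model's classes;
* ``class_level`` — twice the mean is shared equally across all donor
  classes directly.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .windows import LabeledDataset

#: Training label used for every model's complement class.
COMPLEMENT_LABEL = "~other"

MODEL_NAMES = ("Morning", "Afternoon", "Evening", "Mixed")
_ROUTINE_TO_MODEL = {("M",): "Morning", ("A",): "Afternoon", ("E",): "Evening"}


@dataclass(frozen=True)
class BaseModelSpec:
    """One base model's class coverage: main classes plus the complement."""

    index: int
    name: str
    main_classes: tuple[str, ...]
    complement_members: tuple[str, ...]

    def __post_init__(self) -> None:
        overlap = set(self.main_classes) & set(self.complement_members)
        if overlap:
            raise ValidationError(f"model {self.name}: classes in both main and complement: {overlap}")

    @property
    def output_count(self) -> int:
        """Number of network outputs: main classes + the complement class."""
        return len(self.main_classes) + 1

    def covers(self, class_id: str) -> bool:
        return class_id in self.main_classes


def build_model_specs(catalog: dict[str, tuple[str, ...]]) -> list[BaseModelSpec]:
    """Partition a routine-tagged catalog into the four base-model specs.

    ``catalog`` maps class id -> routine tags (subset of {"M", "A", "E"}).
    """
    members: dict[str, list[str]] = {name: [] for name in MODEL_NAMES}
    for class_id, routines in catalog.items():
        if not routines:
            raise ValidationError(f"class {class_id!r} has no routine tags")
        model = _ROUTINE_TO_MODEL.get(tuple(sorted(routines, key="MAE".index)), "Mixed")
        members[model].append(class_id)
    all_classes = list(catalog)
    specs = []
    for index, name in enumerate(MODEL_NAMES, start=1):
        main = tuple(members[name])
        if not main:
            raise ValidationError(f"model {name} has no main classes for this catalog")
        complement = tuple(c for c in all_classes if c not in main)
        specs.append(BaseModelSpec(index, name, main, complement))
    return specs


def spec_for_class(class_id: str, specs: list[BaseModelSpec]) -> BaseModelSpec:
    """The unique base model whose main classes contain ``class_id``."""
    for spec in specs:
        if spec.covers(class_id):
            return spec
    raise ValidationError(f"class {class_id!r} is in no model's main classes")


# ---------------------------------------------------------------------------
# Allocation arithmetic
# ---------------------------------------------------------------------------


def round_half_up(x: float) -> int:
    return math.floor(x + 0.5)


def apportion(total: int, n: int) -> list[int]:
    """Split ``total`` into ``n`` near-equal integer shares (sum preserved).

    Equal quotas with largest-remainder assignment; because quotas are
    equal the extra units go to the last ``total % n`` slots.
    """
    if n <= 0:
        raise ValidationError("cannot apportion over zero slots")
    base, extra = divmod(total, n)
    return [base] * (n - extra) + [base + 1] * extra


def average_main_instances(spec: BaseModelSpec, train_counts: dict[str, float]) -> float:
    """Arithmetic mean of the model's main-class training counts."""
    if not spec.main_classes:
        raise ValidationError(f"model {spec.name} has no main classes")
    missing = [c for c in spec.main_classes if c not in train_counts]
    if missing:
        raise ValidationError(f"main classes missing from training counts: {missing}")
    return float(np.mean([train_counts[c] for c in spec.main_classes]))


@dataclass
class ComplementAllocation:
    """How many donor instances each class contributes to one complement."""

    model_index: int
    scheme: str
    per_class: dict[str, int] = field(default_factory=dict)
    per_model: dict[str, int] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return sum(self.per_class.values())


def class_level_raw_share(avg: float, n_remaining: int) -> float:
    """Pre-rounding per-donor-class share: 2 * avg / n_remaining."""
    if n_remaining <= 0:
        raise ValidationError("no remaining classes to allocate over")
    return 2.0 * avg / n_remaining


def allocate_class_level(
    avg: float, remaining_classes: list[str], model_index: int = 0,
    donor_models: dict[str, list[str]] | None = None,
) -> ComplementAllocation:
    """Equal per-donor-class allocation: round_half_up(2 * avg / n_classes)."""
    if not remaining_classes:
        raise ValidationError("no remaining classes to allocate over")
    if avg <= 0:
        raise ValidationError("average main-class count must be positive")
    per = round_half_up(class_level_raw_share(avg, len(remaining_classes)))
    if per == 0:
        warnings.warn("class-level allocation degenerated to 0 instances per class")
    per_class = {c: per for c in remaining_classes}
    per_model = {}
    if donor_models:
        per_model = {
            name: sum(per_class[c] for c in classes) for name, classes in donor_models.items()
        }
    return ComplementAllocation(model_index, "class_level", per_class, per_model)


def allocate_model_level(
    avg_total: float, remaining_specs: list[BaseModelSpec], model_index: int = 0
) -> ComplementAllocation:
    """Equal per-donor-model allocation of floor(avg_total) instances.

    The floored total is apportioned across donor models, and each model's
    share across its main classes, both by largest remainder (extras to the
    later slots).
    """
    if not remaining_specs:
        raise ValidationError("no remaining models to allocate over")
    total = math.floor(avg_total)
    model_shares = apportion(total, len(remaining_specs))
    per_class: dict[str, int] = {}
    per_model: dict[str, int] = {}
    for spec, share in zip(remaining_specs, model_shares):
        per_model[spec.name] = share
        for class_id, count in zip(spec.main_classes, apportion(share, len(spec.main_classes))):
            per_class[class_id] = count
    return ComplementAllocation(model_index, "model_level", per_class, per_model)


def complement_allocation(
    spec: BaseModelSpec,
    specs: list[BaseModelSpec],
    train_counts: dict[str, float],
    scheme: str,
) -> ComplementAllocation:
    """Allocate complement-class instances for ``spec`` under ``scheme``."""
    remaining_specs = [s for s in specs if s.index != spec.index]
    avg = average_main_instances(spec, train_counts)
    if scheme == "model_level":
        allocation = allocate_model_level(avg, remaining_specs, spec.index)
    elif scheme == "class_level":
        donor_models = {s.name: list(s.main_classes) for s in remaining_specs}
        allocation = allocate_class_level(
            avg, list(spec.complement_members), spec.index, donor_models
        )
    else:
        raise ValidationError(f"unknown complement scheme {scheme!r}")
    return allocation


def sample_complement(
    allocation: ComplementAllocation,
    train_pool: LabeledDataset,
    seed: int = 0,
) -> LabeledDataset:
    """Draw the allocated instances per donor class, relabelled as complement.

    Sampling is without replacement; if a donor class cannot cover its
    allocation the deficit is drawn with replacement and a warning is
    emitted.
    """
    rng = np.random.default_rng(seed)
    labels = train_pool.y.astype(str)
    chosen: list[int] = []
    for class_id, count in allocation.per_class.items():
        if count == 0:
            continue
        members = np.flatnonzero(labels == class_id)
        if len(members) == 0:
            raise ValidationError(f"donor class {class_id!r} absent from the training pool")
        if count <= len(members):
            chosen.extend(rng.choice(members, size=count, replace=False).tolist())
        else:
            warnings.warn(
                f"donor class {class_id!r}: allocation {count} exceeds pool {len(members)}; "
                "sampling deficit with replacement"
            )
            chosen.extend(members.tolist())
            chosen.extend(rng.choice(members, size=count - len(members), replace=True).tolist())
    subset = train_pool.subset(chosen)
    return subset.relabel({str(label): COMPLEMENT_LABEL for label in subset.y})
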