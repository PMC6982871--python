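"""Catalog restructuring: class merges, under-representation filter, splits.

Merges run before the filter — several merge sources individually fall
below the instance threshold yet their merged class clears it, so the
opposite order would delete classes that belong in the final catalog.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

import numpy as np
import yaml

from .catalogs import MERGE_MAP, MIN_INSTANCES
from .errors import ValidationError
from .windows import LabeledDataset

ClassCounts = dict[str, int]


def apply_merges(counts: ClassCounts, merges: dict[str, list[str]]) -> ClassCounts:
    """Replace each merge's source classes with their summed new class."""
    sources_seen: set[str] = set()
    for new_id, sources in merges.items():
        if new_id in counts:
            raise ValidationError(f"merge target {new_id!r} already exists in counts")
        for source in sources:
            if source not in counts:
                raise ValidationError(f"merge source {source!r} missing from counts")
            if source in sources_seen:
                raise ValidationError(f"merge source {source!r} used twice")
            sources_seen.add(source)
    merged = {k: v for k, v in counts.items() if k not in sources_seen}
    for new_id, sources in merges.items():
        merged[new_id] = sum(counts[s] for s in sources)
    return merged


def filter_classes(
    counts: ClassCounts, min_instances: int = MIN_INSTANCES
) -> tuple[ClassCounts, ClassCounts, float]:
    """Drop classes with fewer than ``min_instances`` instances.

    Returns (kept, removed, removed percentage of the original total).
    """
    if min_instances < 0:
        raise ValidationError("min_instances must be non-negative")
    kept = {k: v for k, v in counts.items() if v >= min_instances}
    removed = {k: v for k, v in counts.items() if v < min_instances}
    total = sum(counts.values())
    removed_fraction = 100.0 * sum(removed.values()) / total if total else 0.0
    return kept, removed, removed_fraction


def label_merge_table(merges: dict[str, list[str]]) -> dict[str, str]:
    """Invert a merge map into a source-label -> new-label table."""
    return {source: new_id for new_id, sources in merges.items() for source in sources}


@dataclass
class RestructurePlan:
    """Merges + threshold + split settings, loadable from YAML."""

    merge_map: dict[str, list[str]] = field(default_factory=lambda: dict(MERGE_MAP))
    min_instances: int = MIN_INSTANCES
    test_fraction: float = 0.15
    seed: int = 0

    @classmethod
    def from_yaml(cls, source: Union[str, Path]) -> "RestructurePlan":
        with open(source, "r", encoding="utf-8") as handle:
            raw = yaml.safe_load(handle) or {}
        return cls(
            merge_map={k: list(v) for k, v in raw.get("merge_map", MERGE_MAP).items()},
            min_instances=int(raw.get("min_instances", MIN_INSTANCES)),
            test_fraction=float(raw.get("test_fraction", 0.15)),
            seed=int(raw.get("seed", 0)),
        )

    def to_yaml(self, path: Union[str, Path]) -> None:
        with open(path, "w", encoding="utf-8") as handle:
            yaml.safe_dump(
                {
                    "merge_map": self.merge_map,
                    "min_instances": self.min_instances,
                    "test_fraction": self.test_fraction,
                    "seed": self.seed,
                },
                handle,
            )

    def restructure_counts(self, counts: ClassCounts) -> tuple[ClassCounts, ClassCounts, float]:
        merged = apply_merges(counts, self.merge_map)
        return filter_classes(merged, self.min_instances)

    def restructure_dataset(self, dataset: LabeledDataset) -> LabeledDataset:
        """Relabel merge sources, then drop instances of removed classes."""
        relabeled = dataset.relabel(label_merge_table(self.merge_map))
        kept, _, _ = filter_classes(relabeled.class_counts(), self.min_instances)
        mask = np.isin(relabeled.y.astype(str), list(kept))
        return relabeled.subset(np.flatnonzero(mask))


def split_train_test(
    dataset: LabeledDataset,
    test_fraction: float = 0.15,
    seed: int = 0,
    stratify: bool = False,
) -> tuple[LabeledDataset, LabeledDataset]:
    """Uniform random held-out split; ``round(test_fraction * N)`` test rows.

    ``stratify=True`` draws the test rows per class instead (each class
    contributes round(test_fraction * count), adjusted to the global size).
    """
    if not 0 < test_fraction < 1:
        raise ValidationError("test_fraction must lie strictly between 0 and 1")
    n = len(dataset)
    if n < 2:
        raise ValidationError("need at least 2 instances to split")
    n_test = int(round(test_fraction * n))
    n_test = min(max(n_test, 1), n - 1)
    rng = np.random.default_rng(seed)
    if stratify:
        test_idx: list[int] = []
        labels = dataset.y.astype(str)
        for label in np.unique(labels):
            members = np.flatnonzero(labels == label)
            take = int(round(test_fraction * len(members)))
            test_idx.extend(rng.choice(members, size=take, replace=False).tolist())
        test_idx = sorted(test_idx)
    else:
        test_idx = sorted(rng.choice(n, size=n_test, replace=False).tolist())
    mask = np.zeros(n, dtype=bool)
    mask[test_idx] = True
    return dataset.subset(np.flatnonzero(~mask)), dataset.subset(np.flatnonzero(mask))
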