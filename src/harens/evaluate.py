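"""Experiment harness: repeated folds, conflict accounting and accuracies.

A *fold* is one independent repetition: a fresh random held-out split, a
fresh complement sample and fresh network initialisations, all derived
from the base seed.  Per fold the harness reports the number of conflicts
and, per resolution strategy, the accuracy plus the verdict counts:

* ``correct`` — the fused decision equals the truth;
* ``incorrect`` — the truth class's own (target) model got it wrong, so no
  resolution rule could have recovered the instance;
* ``right_but_incorrect`` — the target model predicted the truth but lost
  the final decision.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .conflict import STRATEGIES, decide_batch, detect
from .ensemble import (
    BaseModelOutput,
    Hyperparams,
    TrainedBaseModel,
    batch_outputs,
    train_base_model,
)
from .errors import ValidationError
from .modelspec import (
    BaseModelSpec,
    build_model_specs,
    complement_allocation,
    sample_complement,
    spec_for_class,
)
from .restructure import split_train_test
from .windows import LabeledDataset

VERDICTS = ("correct", "incorrect", "right_but_incorrect")

_ROUTINE_CODES = {0.0: "M", 0.5: "A", 1.0: "E"}


def infer_catalog(dataset: LabeledDataset, min_share: float = 0.05) -> dict[str, tuple[str, ...]]:
    """Recover per-class routine tags from the dataset's routine feature.

    A class is tagged with every routine holding at least ``min_share`` of
    its instances (guards against stray boundary windows).
    """
    if "routine" not in dataset.feature_names:
        raise ValidationError("dataset has no 'routine' feature column")
    column = dataset.X[:, dataset.feature_names.index("routine")]
    labels = dataset.y.astype(str)
    catalog: dict[str, tuple[str, ...]] = {}
    for label in np.unique(labels):
        values = column[labels == label]
        tags = [
            tag
            for code, tag in _ROUTINE_CODES.items()
            if np.mean(values == code) >= min_share
        ]
        catalog[label] = tuple(tags)
    return catalog


def accuracy(decision_labels: Sequence[str], truths: Sequence[str]) -> float:
    if len(decision_labels) != len(truths):
        raise ValidationError("decision and truth lengths differ")
    if len(truths) == 0:
        raise ValidationError("cannot score an empty test set")
    return float(np.mean(np.asarray(decision_labels) == np.asarray(truths)))


def target_model_of(truth_class: str, specs: Sequence[BaseModelSpec]) -> int:
    """Index of the unique base model owning ``truth_class``."""
    return spec_for_class(truth_class, list(specs)).index


def classify_case(
    outputs: Sequence[BaseModelOutput],
    decision_label: str,
    truth: str,
    specs: Sequence[BaseModelSpec],
) -> str:
    """Verdict for one test instance under one strategy."""
    if decision_label == truth:
        return "correct"
    target = target_model_of(truth, specs)
    target_output = next(o for o in outputs if o.model_index == target)
    if target_output.predicted_class == truth:
        return "right_but_incorrect"
    return "incorrect"


@dataclass
class StrategyOutcome:
    accuracy: float
    correct: int
    incorrect: int
    right_but_incorrect: int


@dataclass
class FoldResult:
    fold: int
    scheme: str
    conflicts: int
    baseline_accuracy: float  # every conflict scored as an error
    per_strategy: dict[str, StrategyOutcome] = field(default_factory=dict)


@dataclass
class ExperimentConfig:
    dataset: LabeledDataset
    catalog: dict[str, tuple[str, ...]]
    scheme: str = "class_level"
    strategies: tuple[str, ...] = STRATEGIES
    folds: int = 10
    test_fraction: float = 0.15
    base_seed: int = 0
    hyperparams: Hyperparams = field(default_factory=Hyperparams)


def _fold_seed(base_seed: int, fold: int, salt: int) -> int:
    return (base_seed * 1_000_003 + fold * 1_009 + salt) % (2**31)


def train_fold_models(
    train: LabeledDataset,
    specs: Sequence[BaseModelSpec],
    scheme: str,
    hyperparams: Hyperparams,
    base_seed: int,
    fold: int = 0,
) -> list[TrainedBaseModel]:
    """Train the four base models for one fold (complements included)."""
    train_counts = {k: float(v) for k, v in train.class_counts().items()}
    labels = train.y.astype(str)
    models = []
    for spec in specs:
        main = train.subset(np.flatnonzero(np.isin(labels, spec.main_classes)))
        allocation = complement_allocation(spec, list(specs), train_counts, scheme)
        complement = sample_complement(
            allocation, train, seed=_fold_seed(base_seed, fold, 10 + spec.index)
        )
        models.append(
            train_base_model(
                spec,
                main,
                complement,
                hyperparams.replace_seed(_fold_seed(base_seed, fold, 20 + spec.index)),
            )
        )
    return models


def run_fold(config: ExperimentConfig, fold: int) -> FoldResult:
    specs = build_model_specs(config.catalog)
    train, test = split_train_test(
        config.dataset, config.test_fraction, seed=_fold_seed(config.base_seed, fold, 1)
    )
    models = train_fold_models(
        train, specs, config.scheme, config.hyperparams, config.base_seed, fold
    )
    outputs = batch_outputs(models, test.X)
    truths = test.y.astype(str)

    cases = [detect(instance_outputs, i) for i, instance_outputs in enumerate(outputs)]
    conflict_mask = np.array([case.is_conflict for case in cases])
    conflicts = int(conflict_mask.sum())

    # Baseline: conflicts always scored wrong; non-conflict routes unchanged.
    reference = decide_batch(outputs, specs, "alg2", models)
    baseline_hits = sum(
        1
        for i, decision in enumerate(reference)
        if not conflict_mask[i] and decision.label == truths[i]
    )
    result = FoldResult(fold, config.scheme, conflicts, baseline_hits / len(test))

    for strategy in config.strategies:
        decisions = decide_batch(outputs, specs, strategy, models)
        labels = [d.label for d in decisions]
        verdicts = [
            classify_case(outputs[i], labels[i], truths[i], specs) for i in range(len(test))
        ]
        result.per_strategy[strategy] = StrategyOutcome(
            accuracy=accuracy(labels, truths),
            correct=verdicts.count("correct"),
            incorrect=verdicts.count("incorrect"),
            right_but_incorrect=verdicts.count("right_but_incorrect"),
        )
    return result


def run_experiment(config: ExperimentConfig) -> list[FoldResult]:
    if config.folds < 1:
        raise ValidationError("need at least one fold")
    return [run_fold(config, fold) for fold in range(1, config.folds + 1)]


# ---------------------------------------------------------------------------
# Tabulation
# ---------------------------------------------------------------------------


def summarize(results: Sequence[FoldResult]) -> pd.DataFrame:
    """Long-form table: one row per fold x strategy, plus per-fold conflicts."""
    rows = []
    for result in results:
        for strategy, outcome in result.per_strategy.items():
            rows.append(
                {
                    "fold": result.fold,
                    "scheme": result.scheme,
                    "conflicts": result.conflicts,
                    "baseline_accuracy": result.baseline_accuracy,
                    "strategy": strategy,
                    "accuracy": outcome.accuracy,
                    "correct": outcome.correct,
                    "incorrect": outcome.incorrect,
                    "right_but_incorrect": outcome.right_but_incorrect,
                }
            )
    return pd.DataFrame(rows)


def averages(results: Sequence[FoldResult]) -> pd.DataFrame:
    """Per-strategy means over folds (conflicts averaged once per fold)."""
    frame = summarize(results)
    grouped = (
        frame.groupby("strategy")[["accuracy", "incorrect", "right_but_incorrect"]]
        .mean()
        .reset_index()
    )
    grouped["mean_conflicts"] = frame.drop_duplicates("fold")["conflicts"].mean()
    grouped["mean_baseline_accuracy"] = frame.drop_duplicates("fold")["baseline_accuracy"].mean()
    return grouped
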