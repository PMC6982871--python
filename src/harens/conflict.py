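"""Conflict detection and the four resolution strategies.

A conflict arises when two or more base models each assert one of their own
main classes for the same instance.  Each strategy scores the conflicting
(claimant) models and awards the decision to the highest score; for two
claimants this reduces to the pairwise if/else comparison, and for three or
more it is the order-independent argmax generalisation.  Score ties break
toward the lowest model index.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .ensemble import BaseModelOutput, TrainedBaseModel
from .errors import ValidationError
from .modelspec import COMPLEMENT_LABEL, BaseModelSpec

STRATEGIES = ("alg2", "alg3", "alg4", "alg5")

ROUTE_SINGLE = "single_claimant"
ROUTE_FALLBACK = "fallback_no_claimant"


@dataclass
class ConflictCase:
    """An instance's four outputs plus the models asserting a main class."""

    index: int
    claimants: list[int]
    outputs: list[BaseModelOutput]

    @property
    def is_conflict(self) -> bool:
        return len(self.claimants) >= 2

    def output_of(self, model_index: int) -> BaseModelOutput:
        for output in self.outputs:
            if output.model_index == model_index:
                return output
        raise ValidationError(f"no output for model {model_index}")


@dataclass(frozen=True)
class FinalDecision:
    index: int
    label: str
    route: str
    winner: int

    def __post_init__(self) -> None:
        if self.label == COMPLEMENT_LABEL:
            raise ValidationError("final decision must be a main class, not the complement")


def detect(outputs: Sequence[BaseModelOutput], index: int = 0) -> ConflictCase:
    """Collect the models whose argmax output is a main class."""
    claimants = sorted(o.model_index for o in outputs if o.asserts_main_class)
    return ConflictCase(index, claimants, list(outputs))


# ---------------------------------------------------------------------------
# Claimant scores, one per strategy
# ---------------------------------------------------------------------------


def _score_highest(output: BaseModelOutput, spec: BaseModelSpec, acc: float) -> float:
    return output.p1


def _score_margin(output: BaseModelOutput, spec: BaseModelSpec, acc: float) -> float:
    return output.p1 - output.p2


def _score_class_weighted(output: BaseModelOutput, spec: BaseModelSpec, acc: float) -> float:
    return output.p1 * spec.output_count


def _score_acc_weighted(output: BaseModelOutput, spec: BaseModelSpec, acc: float) -> float:
    return output.p1 * spec.output_count * acc


_SCORES: dict[str, Callable[[BaseModelOutput, BaseModelSpec, float], float]] = {
    "alg2": _score_highest,
    "alg3": _score_margin,
    "alg4": _score_class_weighted,
    "alg5": _score_acc_weighted,
}


def _resolve(
    case: ConflictCase,
    strategy: str,
    specs: Sequence[BaseModelSpec],
    accuracies: dict[int, float] | None,
) -> FinalDecision:
    if not case.is_conflict:
        raise ValidationError("resolution requires at least 2 claimants")
    spec_by_index = {s.index: s for s in specs}
    score = _SCORES[strategy]
    best_index, best_score = -1, -np.inf
    for j in case.claimants:  # ascending: ties keep the lowest model index
        acc = 1.0
        if strategy == "alg5":
            if accuracies is None or j not in accuracies:
                raise ValidationError(f"training accuracy missing for model {j}")
            acc = accuracies[j]
        value = score(case.output_of(j), spec_by_index[j], acc)
        if value > best_score:
            best_index, best_score = j, value
    winner = case.output_of(best_index)
    return FinalDecision(case.index, winner.predicted_class, f"resolved_{strategy}", best_index)


def resolve_highest(case: ConflictCase, specs: Sequence[BaseModelSpec]) -> FinalDecision:
    """Award the decision to the claimant with the largest p1."""
    return _resolve(case, "alg2", specs, None)


def resolve_margin(case: ConflictCase, specs: Sequence[BaseModelSpec]) -> FinalDecision:
    """Award the decision to the claimant with the largest p1 - p2 margin."""
    return _resolve(case, "alg3", specs, None)


def resolve_class_weighted(case: ConflictCase, specs: Sequence[BaseModelSpec]) -> FinalDecision:
    """Award the decision to the claimant with the largest p1 * m_j."""
    return _resolve(case, "alg4", specs, None)


def resolve_acc_weighted(
    case: ConflictCase, specs: Sequence[BaseModelSpec], accuracies: dict[int, float]
) -> FinalDecision:
    """Award the decision to the claimant with the largest p1 * m_j * Acctrain_j."""
    return _resolve(case, "alg5", specs, accuracies)


def _fallback(case: ConflictCase, specs: Sequence[BaseModelSpec]) -> FinalDecision:
    """No model asserted a main class: take the globally most probable main class."""
    spec_by_index = {s.index: s for s in specs}
    best = (-np.inf, -1, "")
    for output in case.outputs:
        spec = spec_by_index[output.model_index]
        for class_id, probability in zip(output.classes, output.probabilities):
            if class_id == COMPLEMENT_LABEL or class_id not in spec.main_classes:
                continue
            if probability > best[0]:
                best = (float(probability), output.model_index, class_id)
    if best[1] < 0:
        raise ValidationError("no main-class probabilities available for fallback")
    return FinalDecision(case.index, best[2], ROUTE_FALLBACK, best[1])


def decide(
    outputs: Sequence[BaseModelOutput],
    specs: Sequence[BaseModelSpec],
    strategy: str,
    accuracies: dict[int, float] | None = None,
    index: int = 0,
) -> FinalDecision:
    """Full per-instance decision: single claimant, resolver, or fallback."""
    if strategy not in STRATEGIES:
        raise ValidationError(f"unknown strategy {strategy!r}; expected one of {STRATEGIES}")
    case = detect(outputs, index)
    if len(case.claimants) == 1:
        winner = case.output_of(case.claimants[0])
        return FinalDecision(index, winner.predicted_class, ROUTE_SINGLE, winner.model_index)
    if not case.claimants:
        return _fallback(case, specs)
    return _resolve(case, strategy, specs, accuracies)


def decide_batch(
    per_instance_outputs: Sequence[Sequence[BaseModelOutput]],
    specs: Sequence[BaseModelSpec],
    strategy: str,
    models: Sequence[TrainedBaseModel] | None = None,
) -> list[FinalDecision]:
    accuracies = (
        {m.spec.index: m.train_accuracy for m in models} if models is not None else None
    )
    return [
        decide(outputs, specs, strategy, accuracies, index=i)
        for i, outputs in enumerate(per_instance_outputs)
    ]
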