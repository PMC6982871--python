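"""Conflict detection and resolution, checked against independent oracles.

The oracle implements the published pairwise if/else comparisons directly
(left-to-right over the claimant list) and, separately, verifies that any
returned winner's score is maximal.  Both stay independent of the package's
argmax implementation.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from harens import (
    COMPLEMENT_LABEL,
    BaseModelOutput,
    ValidationError,
    decide,
    detect,
    resolve_acc_weighted,
    resolve_class_weighted,
    resolve_highest,
    resolve_margin,
)
from harens.conflict import ConflictCase, FinalDecision, ROUTE_FALLBACK, ROUTE_SINGLE
from harens.modelspec import BaseModelSpec

# A fixed 4-model universe for constructing outputs by hand: model j has
# j main classes "Mj_k" plus the complement.
SPECS = [
    BaseModelSpec(j, name, tuple(f"M{j}_{k}" for k in range(j)),
                  tuple(f"M{i}_{k}" for i in range(1, 5) if i != j for k in range(i)))
    for j, name in enumerate(["Morning", "Afternoon", "Evening", "Mixed"], start=1)
]


def _output(j: int, probabilities, main_argmax=True) -> BaseModelOutput:
    """Build an output for model j; last slot is the complement class."""
    probabilities = np.asarray(probabilities, dtype=float)
    classes = tuple(f"M{j}_{k}" for k in range(len(probabilities) - 1)) + (COMPLEMENT_LABEL,)
    return BaseModelOutput(j, classes, probabilities / probabilities.sum())


def _complement_output(j: int) -> BaseModelOutput:
    probabilities = np.full(j + 1, 0.1 / j)
    probabilities[-1] = 0.9
    classes = tuple(f"M{j}_{k}" for k in range(j)) + (COMPLEMENT_LABEL,)
    return BaseModelOutput(j, classes, probabilities / probabilities.sum())


# ---------------------------------------------------------------------------
# Detection
# ---------------------------------------------------------------------------


def test_single_claimant_no_conflict():
    outputs = [_output(1, [0.8, 0.1, 0.1])] + [_complement_output(j) for j in (2, 3, 4)]
    case = detect(outputs)
    assert case.claimants == [1] and not case.is_conflict


def test_two_claimants_conflict():
    outputs = [
        _output(1, [0.8, 0.1, 0.1]),
        _output(2, [0.5, 0.3, 0.2]),
        _complement_output(3),
        _complement_output(4),
    ]
    case = detect(outputs)
    assert case.is_conflict and case.claimants == [1, 2]


def test_zero_claimants():
    case = detect([_complement_output(j) for j in (1, 2, 3, 4)])
    assert case.claimants == [] and not case.is_conflict


# ---------------------------------------------------------------------------
# Published worked examples
# ---------------------------------------------------------------------------


def test_highest_prediction_wins():
    case = ConflictCase(0, [1, 2], [_output(1, [0.9, 0.05, 0.05]), _output(2, [0.7, 0.2, 0.1])])
    assert resolve_highest(case, SPECS).winner == 1


def test_highest_tie_goes_to_lowest_model_index():
    case = ConflictCase(0, [2, 3], [_output(2, [0.6, 0.3, 0.1]), _output(3, [0.6, 0.2, 0.1, 0.1])])
    assert resolve_highest(case, SPECS).winner == 2


def test_margin_prefers_confident_model():
    # top-two 0.56/0.54 vs 0.48/0.10: the small-margin model loses
    weak = _output(1, [0.56, 0.54, 0.0])
    strong = _output(2, [0.48, 0.10, 0.42])
    case = ConflictCase(0, [1, 2], [weak, strong])
    decision = resolve_margin(case, SPECS)
    assert decision.winner == 2
    # while the raw-highest rule would have chosen the weak model
    assert resolve_highest(case, SPECS).winner == 1


def test_class_weighting_example():
    # m=2 with p1=0.9 (1.8) loses to m=8 with p1=0.3 (2.4)
    small = _output(1, [0.9, 0.1])  # 1 main class + complement -> m=2
    big_probabilities = np.full(8, 0.1)
    big_probabilities[0] = 0.3
    big = BaseModelOutput(4, tuple(f"M4_{k}" for k in range(7)) + (COMPLEMENT_LABEL,),
                          big_probabilities / big_probabilities.sum())
    # renormalisation keeps p1=0.3 exact
    assert big.p1 == pytest.approx(0.3)
    case = ConflictCase(0, [1, 4], [small, big])
    specs = [
        BaseModelSpec(1, "Afternoon-like", ("M1_0",), ()),          # m = 2
        BaseModelSpec(4, "Mixed-like", tuple(f"M4_{k}" for k in range(7)), ()),  # m = 8
    ]
    assert resolve_class_weighted(case, specs).winner == 4


def test_accuracy_weighting_breaks_symmetry():
    # equal p1 and equal m: the higher-training-accuracy model wins
    equal_specs = [BaseModelSpec(j, f"S{j}", (f"M{j}_0", f"M{j}_1"), ()) for j in (2, 3)]
    a = BaseModelOutput(2, ("M2_0", "M2_1", COMPLEMENT_LABEL), np.array([0.8, 0.1, 0.1]))
    b = BaseModelOutput(3, ("M3_0", "M3_1", COMPLEMENT_LABEL), np.array([0.8, 0.1, 0.1]))
    case = ConflictCase(0, [2, 3], [a, b])
    assert resolve_acc_weighted(case, equal_specs, {2: 0.6, 3: 0.9}).winner == 3


def test_acc_weighted_requires_accuracies():
    case = ConflictCase(0, [1, 2], [_output(1, [0.9, 0.05, 0.05]), _output(2, [0.7, 0.2, 0.1])])
    with pytest.raises(ValidationError):
        resolve_acc_weighted(case, SPECS, {1: 0.9})


def test_resolution_requires_two_claimants():
    case = ConflictCase(0, [1], [_output(1, [0.9, 0.05, 0.05])])
    with pytest.raises(ValidationError):
        resolve_highest(case, SPECS)


# ---------------------------------------------------------------------------
# Oracle comparison
# ---------------------------------------------------------------------------


def _oracle_pairwise(case, score_of):
    """Left-to-right chain of the published pairwise if/else rule."""
    winner = case.claimants[0]
    for challenger in case.claimants[1:]:
        # strict '>' keeps the incumbent on ties, matching lowest-index rule
        if score_of(challenger) > score_of(winner):
            winner = challenger
    return winner


def _random_case(rng, n_claimants):
    models = sorted(rng.choice([1, 2, 3, 4], size=n_claimants, replace=False).tolist())
    outputs = []
    for j in models:
        probabilities = rng.dirichlet(np.ones(j + 1))
        # force a main-class argmax so the model is a claimant
        top = int(np.argmax(probabilities))
        if top == j:
            probabilities[[0, j]] = probabilities[[j, 0]]
        outputs.append(_output(j, probabilities))
    return ConflictCase(0, models, outputs)


def _score_functions(case, accuracies):
    m = {s.index: s.output_count for s in SPECS}
    return {
        "alg2": lambda j: case.output_of(j).p1,
        "alg3": lambda j: case.output_of(j).p1 - case.output_of(j).p2,
        "alg4": lambda j: case.output_of(j).p1 * m[j],
        "alg5": lambda j: case.output_of(j).p1 * m[j] * accuracies[j],
    }


@pytest.mark.parametrize("n_claimants", [2, 3])
def test_resolvers_match_pairwise_oracle(rng, n_claimants):
    accuracies = {j: 0.5 + 0.5 * rng.random() for j in (1, 2, 3, 4)}
    resolvers = {
        "alg2": lambda c: resolve_highest(c, SPECS),
        "alg3": lambda c: resolve_margin(c, SPECS),
        "alg4": lambda c: resolve_class_weighted(c, SPECS),
        "alg5": lambda c: resolve_acc_weighted(c, SPECS, accuracies),
    }
    for _ in range(300):
        case = _random_case(rng, n_claimants)
        scores = _score_functions(case, accuracies)
        for name, resolver in resolvers.items():
            decision = resolver(case)
            expected = _oracle_pairwise(case, scores[name])
            assert decision.winner == expected, name
            assert decision.label == case.output_of(expected).predicted_class


def test_limit_equivalences(rng):
    """Equal m: alg4 == alg2.  Equal accuracies: alg5 == alg4."""
    equal_m_specs = [BaseModelSpec(j, f"S{j}", (f"M{j}_0", f"M{j}_1"), ()) for j in (1, 2, 3, 4)]
    for _ in range(200):
        models = sorted(rng.choice([1, 2, 3, 4], size=2, replace=False).tolist())
        outputs = []
        for j in models:
            probabilities = rng.dirichlet(np.ones(3))
            top = int(np.argmax(probabilities))
            if top == 2:
                probabilities[[0, 2]] = probabilities[[2, 0]]
            outputs.append(BaseModelOutput(j, (f"M{j}_0", f"M{j}_1", COMPLEMENT_LABEL), probabilities))
        case = ConflictCase(0, models, outputs)
        assert resolve_class_weighted(case, equal_m_specs).winner == \
            resolve_highest(case, equal_m_specs).winner
        accs = {j: 0.77 for j in models}
        assert resolve_acc_weighted(case, equal_m_specs, accs).winner == \
            resolve_class_weighted(case, equal_m_specs).winner


# ---------------------------------------------------------------------------
# decide(): routing
# ---------------------------------------------------------------------------


def test_decide_single_claimant_route():
    outputs = [_output(3, [0.1, 0.7, 0.1, 0.1])] + [_complement_output(j) for j in (1, 2, 4)]
    decision = decide(outputs, SPECS, "alg2")
    assert decision.route == ROUTE_SINGLE
    assert decision.winner == 3 and decision.label == "M3_1"


def test_decide_fallback_on_all_complements():
    outputs = [_complement_output(j) for j in (1, 2, 3, 4)]
    decision = decide(outputs, SPECS, "alg3")
    assert decision.route == ROUTE_FALLBACK
    assert decision.label != COMPLEMENT_LABEL


def test_decide_conflict_routes_to_strategy():
    outputs = [
        _output(1, [0.9, 0.05, 0.05]),
        _output(2, [0.7, 0.2, 0.1]),
        _complement_output(3),
        _complement_output(4),
    ]
    decision = decide(outputs, SPECS, "alg2")
    assert decision.route == "resolved_alg2" and decision.winner == 1


def test_decide_rejects_unknown_strategy():
    with pytest.raises(ValidationError):
        decide([_complement_output(j) for j in (1, 2, 3, 4)], SPECS, "alg9")


def test_final_decision_never_complement():
    with pytest.raises(ValidationError):
        FinalDecision(0, COMPLEMENT_LABEL, "resolved_alg2", 1)


@settings(max_examples=60, deadline=None)
@given(st.integers(min_value=0, max_value=2**32 - 1), st.sampled_from(["alg2", "alg3", "alg4", "alg5"]))
def test_decide_label_is_main_class_of_winner(seed, strategy):
    rng = np.random.default_rng(seed)
    outputs = []
    for j in (1, 2, 3, 4):
        probabilities = rng.dirichlet(np.ones(j + 1))
        classes = tuple(f"M{j}_{k}" for k in range(j)) + (COMPLEMENT_LABEL,)
        outputs.append(BaseModelOutput(j, classes, probabilities))
    accuracies = {j: float(rng.uniform(0.5, 1.0)) for j in (1, 2, 3, 4)}
    decision = decide(outputs, SPECS, strategy, accuracies)
    assert decision.label != COMPLEMENT_LABEL
    winning_spec = next(s for s in SPECS if s.index == decision.winner)
    assert decision.label in winning_spec.main_classes
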