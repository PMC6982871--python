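"""Feed-forward base classifiers and their probability outputs.

Each base model is a single-hidden-layer network fitted on its main-class
instances plus its sampled complement class.  Its output for an instance is
a probability vector over ``m_j`` classes (main classes + complement); the
largest and second-largest entries (p1, p2) and the argmax class feed the
conflict-resolution stage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.neural_network import MLPClassifier

from .errors import ValidationError
from .modelspec import COMPLEMENT_LABEL, BaseModelSpec
from .windows import LabeledDataset


@dataclass(frozen=True)
class Hyperparams:
    """Network settings; all defaults are declared, logged choices."""

    hidden_units: int = 64
    activation: str = "relu"
    max_epochs: int = 500
    learning_rate: float = 1e-3
    seed: int = 0

    def replace_seed(self, seed: int) -> "Hyperparams":
        return Hyperparams(
            self.hidden_units, self.activation, self.max_epochs, self.learning_rate, seed
        )


@dataclass
class BaseModelOutput:
    """One model's probability vector for one instance."""

    model_index: int
    classes: tuple[str, ...]
    probabilities: np.ndarray

    def __post_init__(self) -> None:
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        if len(self.classes) != len(self.probabilities):
            raise ValidationError("class list and probability vector lengths differ")
        if abs(self.probabilities.sum() - 1.0) > 1e-6:
            raise ValidationError("probabilities do not sum to 1")

    @property
    def p1(self) -> float:
        """Largest output probability."""
        return float(np.max(self.probabilities))

    @property
    def p2(self) -> float:
        """Second-largest output probability (complement column included)."""
        if len(self.probabilities) < 2:
            return 0.0
        return float(np.sort(self.probabilities)[-2])

    @property
    def predicted_class(self) -> str:
        # np.argmax returns the first maximum: ties go to the lowest index.
        return self.classes[int(np.argmax(self.probabilities))]

    @property
    def asserts_main_class(self) -> bool:
        return self.predicted_class != COMPLEMENT_LABEL


@dataclass
class TrainedBaseModel:
    spec: BaseModelSpec
    predictor: MLPClassifier
    train_accuracy: float
    hyperparams: Hyperparams
    classes: tuple[str, ...] = field(init=False)

    def __post_init__(self) -> None:
        self.classes = tuple(str(c) for c in self.predictor.classes_)


def train_base_model(
    spec: BaseModelSpec,
    main_data: LabeledDataset,
    complement_data: LabeledDataset | None,
    hyperparams: Hyperparams = Hyperparams(),
) -> TrainedBaseModel:
    """Fit one base network on main + complement data.

    Raises if any main class has no training instances or if foreign labels
    leak into ``main_data``.  Training is deterministic for a fixed seed.
    """
    counts = main_data.class_counts()
    foreign = set(counts) - set(spec.main_classes)
    if foreign:
        raise ValidationError(f"model {spec.name}: labels outside main classes: {sorted(foreign)}")
    empty = [c for c in spec.main_classes if counts.get(c, 0) == 0]
    if empty:
        raise ValidationError(f"model {spec.name}: main classes with no training data: {empty}")
    parts = [main_data]
    if complement_data is not None and len(complement_data):
        bad = set(complement_data.class_counts()) - {COMPLEMENT_LABEL}
        if bad:
            raise ValidationError(f"complement data carries non-complement labels: {sorted(bad)}")
        parts.append(complement_data)
    train = LabeledDataset.concatenate(parts)

    network = MLPClassifier(
        hidden_layer_sizes=(hyperparams.hidden_units,),
        activation=hyperparams.activation,
        max_iter=hyperparams.max_epochs,
        learning_rate_init=hyperparams.learning_rate,
        solver="adam",
        random_state=hyperparams.seed,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        network.fit(train.X, train.y.astype(str))
    if len(network.classes_) != spec.output_count:
        raise ValidationError(
            f"model {spec.name}: fitted {len(network.classes_)} outputs, expected {spec.output_count}"
        )
    train_accuracy = float(np.mean(network.predict(train.X) == train.y.astype(str)))
    return TrainedBaseModel(spec, network, train_accuracy, hyperparams)


def predict_base(model: TrainedBaseModel, x: np.ndarray) -> BaseModelOutput:
    """Probability output of one base model for a single feature vector."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.shape[0] != model.predictor.n_features_in_:
        raise ValidationError(
            f"expected a length-{model.predictor.n_features_in_} feature vector, got shape {x.shape}"
        )
    probabilities = model.predictor.predict_proba(x.reshape(1, -1))[0]
    return BaseModelOutput(model.spec.index, model.classes, probabilities)


def predict_all(models: list[TrainedBaseModel], x: np.ndarray) -> list[BaseModelOutput]:
    """All base-model outputs for one instance, ordered by model index."""
    return [predict_base(model, x) for model in sorted(models, key=lambda m: m.spec.index)]


def batch_outputs(models: list[TrainedBaseModel], X: np.ndarray) -> list[list[BaseModelOutput]]:
    """Per-instance outputs for a whole matrix (one predict_proba per model)."""
    X = np.asarray(X, dtype=float)
    ordered = sorted(models, key=lambda m: m.spec.index)
    probability_blocks = [model.predictor.predict_proba(X) for model in ordered]
    return [
        [
            BaseModelOutput(model.spec.index, model.classes, block[i])
            for model, block in zip(ordered, probability_blocks)
        ]
        for i in range(len(X))
    ]
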