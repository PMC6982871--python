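"""Shared fixtures: registries, simulated streams, trained small ensembles."""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from harens import (
    ExperimentConfig,
    SensorRegistry,
    build_dataset,
    build_model_specs,
    default_config,
    generate,
)
from harens.evaluate import train_fold_models


@pytest.fixture(scope="session")
def registry() -> SensorRegistry:
    return SensorRegistry.default()


@pytest.fixture(scope="session")
def small_sim():
    """Zero-noise 4-class simulation: (config, events, annotations)."""
    config = default_config("small", seed=7)
    events, annotations = generate(config)
    return config, events, annotations


@pytest.fixture(scope="session")
def small_dataset(small_sim, registry):
    config, events, annotations = small_sim
    return build_dataset(events, annotations, registry)


@pytest.fixture(scope="session")
def small_specs(small_sim):
    config, _, _ = small_sim
    return build_model_specs(config.catalog)


@pytest.fixture(scope="session")
def small_models(small_dataset, small_specs):
    """Four base models trained on the full small dataset (class-level)."""
    from harens.ensemble import Hyperparams

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return train_fold_models(
            small_dataset,
            small_specs,
            scheme="class_level",
            hyperparams=Hyperparams(hidden_units=32, max_epochs=300),
            base_seed=7,
        )


@pytest.fixture(scope="session")
def paper_catalog():
    from harens import RESTRUCTURED_ROUTINES

    return dict(RESTRUCTURED_ROUTINES)


@pytest.fixture(scope="session")
def paper_train_counts():
    """Restructured class counts scaled by the 85% training fraction."""
    from harens import MERGE_MAP, RAW_CLASS_COUNTS, apply_merges, filter_classes

    merged = apply_merges(RAW_CLASS_COUNTS, MERGE_MAP)
    kept, _, _ = filter_classes(merged, 30)
    return {k: 0.85 * v for k, v in kept.items()}


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
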