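"""Shared fixtures.

The trained toy model is session-scoped: one reduced-scale training run
(3 toy Fv fixtures, 2000 steps) feeds both the training-recovery checks
and the template-pipeline checks.
"""

from __future__ import annotations

import numpy as np
import pytest

from abframes.config import ModelConfig, TrainingConfig
from abframes.embeddings import SyntheticEmbedder
from abframes.fixtures import ToySpec, make_toy_fv
from abframes.model import StructurePredictor
from abframes.pipeline import make_toy_dataset, train_toy_model


@pytest.fixture(scope="session")
def toy_config() -> ModelConfig:
    return ModelConfig.toy()


@pytest.fixture(scope="session")
def toy_structure():
    return make_toy_fv(ToySpec(seed=11))


@pytest.fixture(scope="session")
def toy_nanobody():
    return make_toy_fv(ToySpec(light_length=0, seed=5))


@pytest.fixture(scope="session")
def toy_embedder(toy_config):
    return SyntheticEmbedder(toy_config, seed=0)


@pytest.fixture(scope="session")
def untrained_model(toy_config):
    return StructurePredictor(toy_config, seed=1)


@pytest.fixture(scope="session")
def toy_dataset(toy_config):
    return make_toy_dataset(toy_config, n=3, seed=0)


@pytest.fixture(scope="session")
def trained_toy():
    """(model, loss trace, dataset) after the 2000-step toy overfit run."""
    config = ModelConfig.toy()
    training = TrainingConfig.toy(steps=2000, seed=0)
    model, trace = train_toy_model(config, training, n_fixtures=3, data_seed=0)
    dataset = make_toy_dataset(config, n=3, seed=0)
    return model, trace, dataset
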