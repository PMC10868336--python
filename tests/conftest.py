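"""Shared fixtures: a small synthetic world and a briefly trained model.

Everything is generated at test time from seeds; no stored data.
"""
from __future__ import annotations

import numpy as np
import pytest

from phoskin.curation import CurationConfig
from phoskin.model import ModelConfig, MultitaskModel
from phoskin.pipeline import curate_world, train_world_model
from phoskin.synthetic import make_world
from phoskin.training import TrainConfig
from phoskin.vocab import Vocabulary


@pytest.fixture(scope="session")
def vocab() -> Vocabulary:
    return Vocabulary()


@pytest.fixture(scope="session")
def tiny_world():
    """4 families x 3 kinases, short domains — seconds to build."""
    return make_world(n_families=4, kinases_per_family=3, domain_length=40,
                      n_phospho=500, n_nonphospho=250, seed=101)


@pytest.fixture(scope="session")
def tiny_examples(tiny_world):
    return curate_world(tiny_world, CurationConfig(seed=101))


@pytest.fixture(scope="session")
def tiny_model_config():
    return ModelConfig(d_model=32, n_layers=2, n_heads=4, d_ff=64,
                       head_heads=4, seed=101)


@pytest.fixture(scope="session")
def tiny_trained(tiny_world, tiny_examples, tiny_model_config):
    """A briefly trained multitask model plus its loss history."""
    tc = TrainConfig(lr_init=1e-3, epochs=2, task_probability=0.5,
                     batch_size=16, checkpoint_every=0, seed=101)
    model, _, history = train_world_model(
        tiny_world, tiny_examples, tiny_model_config, tc, pretrain_steps=0)
    return model, history


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
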