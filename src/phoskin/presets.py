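"""Canonical study configurations.

Two bundled setups are used throughout the docs, tests and the
reproduction script:

* the *mechanism study*: 8 families x 4 kinases with one bimodal family,
  ~2000 curated positives, a 2-layer d=64 encoder trained 3 epochs with
  multitask batches — the setting for seen-kinase discrimination,
  determinant recovery and motif decomposition;
* the *zero-shot study*: 6 families x 5 kinases (30 kinases, so a 10%
  holdout removes 3), a 2-layer d=32 encoder, used to compare the three
  initialization variants on held-out kinases across seeds.

Domain length is 48/40 and the encoder is small so a full study runs in
minutes on one CPU; docs/methods.md discusses what these scales do and do
not show.
"""
from __future__ import annotations

from .augment import AugmentConfig
from .curation import CurationConfig
from .model import ModelConfig
from .synthetic import SyntheticWorld, make_world
from .training import TrainConfig

#: MLM pretraining steps used by the "pretrained" init variants
MECHANISM_PRETRAIN_STEPS = 100
ZERO_SHOT_PRETRAIN_STEPS = 300


def mechanism_world(seed: int = 0) -> SyntheticWorld:
    return make_world(n_families=8, kinases_per_family=4, domain_length=48,
                      n_phospho=2100, n_nonphospho=400, bimodal_family=0,
                      seed=seed)


def mechanism_model_config(seed: int = 0) -> ModelConfig:
    return ModelConfig(d_model=64, n_layers=2, n_heads=4, d_ff=128,
                       head_heads=4, seed=seed)


def mechanism_train_config(seed: int = 0) -> TrainConfig:
    return TrainConfig(lr_init=1e-3, epochs=3, task_probability=0.5,
                       batch_size=16, checkpoint_every=200, seed=seed)


def zero_shot_world(seed: int = 0) -> SyntheticWorld:
    return make_world(n_families=6, kinases_per_family=5, domain_length=40,
                      n_phospho=700, n_nonphospho=250, seed=seed)


def zero_shot_model_config(seed: int = 0) -> ModelConfig:
    return ModelConfig(d_model=32, n_layers=2, n_heads=4, d_ff=64,
                       head_heads=4, seed=seed)


def zero_shot_train_config(seed: int = 0) -> TrainConfig:
    return TrainConfig(lr_init=1e-3, epochs=3, task_probability=0.5,
                       batch_size=16, checkpoint_every=0, seed=seed)


def default_curation_config(seed: int = 0) -> CurationConfig:
    return CurationConfig(seed=seed)


def default_augment_config(seed: int = 0) -> AugmentConfig:
    return AugmentConfig(seed=seed)
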