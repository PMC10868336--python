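"""End-to-end orchestration: world -> curated dataset -> trained model ->
metrics and attributions.  The CLI and the reproduction script are thin
wrappers over these functions.
"""
from __future__ import annotations

import logging
from pathlib import Path

import numpy as np

from .augment import AugmentConfig
from .curation import (EASY_NEGATIVE, HARD_NEGATIVE, POSITIVE,
                       CurationConfig, PairExample, attach_clusters,
                       check_tier_invariants, cluster_kinases,
                       cluster_peptides_by_center, collect_easy_negatives,
                       label_pairs, make_splits, select_representatives,
                       split_of)
from .evaluation import (discrimination_metrics, easy_negative_fpr,
                         hit_at_1_from_model)
from .interpret import (AttributionVector, PartitionExplainer,
                        motif_decomposition, motif_recovery_rate)
from .model import ModelConfig, MultitaskModel
from .synthetic import SyntheticWorld
from .training import TrainConfig, pretrain_mlm, train

logger = logging.getLogger(__name__)


def curate_world(world: SyntheticWorld,
                 config: CurationConfig | None = None,
                 hard_negative_cap: int | None = None,
                 easy_negative_total: int | None = None
                 ) -> list[PairExample]:
    """Run the full curation pipeline on a synthetic world."""
    config = config or CurationConfig()
    scored = []
    for j, kid in enumerate(world.kinase_ids):
        for i, pep in enumerate(world.phospho_peptides):
            scored.append((kid, pep, float(world.percentiles[i, j])))
    labeled, _ = label_pairs(scored, config)

    kinase_clusters = {a.entity_id: a.cluster_id for a in cluster_kinases(
        world.kinases, config.kinase_identity_threshold)}
    peptide_clusters = cluster_peptides_by_center(
        world.phospho_peptides, config.peptide_hamming_cutoff,
        config.peptide_window)
    attach_clusters(labeled, kinase_clusters, peptide_clusters)

    rng = np.random.default_rng(config.seed)
    positives = select_representatives(
        [e for e in labeled if e.tier == POSITIVE], seed=config.seed)
    hard = select_representatives(
        [e for e in labeled if e.tier == HARD_NEGATIVE],
        seed=config.seed + 1)
    if hard_negative_cap is None:
        hard_negative_cap = len(positives)
    if len(hard) > hard_negative_cap:
        idx = rng.choice(len(hard), size=hard_negative_cap, replace=False)
        hard = [hard[i] for i in sorted(idx)]
    if easy_negative_total is None:
        easy_negative_total = len(positives)
    nonphospho_clusters = cluster_peptides_by_center(
        world.nonphospho_peptides, config.peptide_hamming_cutoff,
        config.peptide_window, pool_tag="N")
    easy = collect_easy_negatives(
        world.kinases, world.nonphospho_peptides, easy_negative_total,
        seed=config.seed + 2, kinase_clusters=kinase_clusters,
        peptide_clusters=nonphospho_clusters, config=config)
    examples = make_splits(positives, hard, easy, config)
    check_tier_invariants(examples, config)
    return examples


def train_world_model(world: SyntheticWorld, examples: list[PairExample],
                      model_config: ModelConfig | None = None,
                      train_config: TrainConfig | None = None,
                      augment_config: AugmentConfig | None = None,
                      pretrain_steps: int = 0, pretrain_lr: float = 1e-3,
                      checkpoint_dir: str | Path | None = None
                      ) -> tuple[MultitaskModel, list[Path], list[dict]]:
    model = MultitaskModel(model_config or ModelConfig())
    if pretrain_steps > 0:
        pretrain_mlm(model, world.mlm_corpus, steps=pretrain_steps,
                     lr_init=pretrain_lr,
                     seed=(train_config or TrainConfig()).seed + 7)
        model.config.init = "pretrained_checkpoint"
    ckpts, history = train(model, examples, world.kinases,
                           world.mlm_corpus, train_config, augment_config,
                           checkpoint_dir=checkpoint_dir)
    return model, ckpts, history


def seen_test_metrics(model: MultitaskModel, examples: list[PairExample],
                      world: SyntheticWorld) -> dict:
    """The kinase-centric benchmark: AUCs/accuracy on the 1:1 positive vs
    hard-negative test slice, FPR on the easy-negative test slice."""
    kinase_seq = {k.kinase_id: k.domain_sequence for k in world.kinases}
    test = split_of(examples, "test")
    scored = [ex for ex in test if ex.tier in (POSITIVE, HARD_NEGATIVE)]
    easy = [ex for ex in test if ex.tier == EASY_NEGATIVE]
    probs = model.predict_pairs(
        [(ex.peptide.sequence, kinase_seq[ex.kinase_id]) for ex in scored])
    labels = np.array([ex.label for ex in scored])
    out = discrimination_metrics(probs, labels)
    if easy:
        easy_probs = model.predict_pairs(
            [(ex.peptide.sequence, kinase_seq[ex.kinase_id]) for ex in easy])
        out["fpr_easy"] = easy_negative_fpr(easy_probs, 0.5)
    out["n_scored"] = len(scored)
    out["n_easy"] = len(easy)
    return out


def substrate_hit1(model: MultitaskModel, examples: list[PairExample],
                   world: SyntheticWorld, max_substrates: int = 60,
                   seed: int = 0) -> dict:
    """Substrate-centric Hit@1: rank all kinases for test-split positive
    substrates; macro-average over family and group classes."""
    test_pos = [ex for ex in split_of(examples, "test")
                if ex.tier == POSITIVE]
    rng = np.random.default_rng(seed)
    if len(test_pos) > max_substrates:
        idx = rng.choice(len(test_pos), size=max_substrates, replace=False)
        test_pos = [test_pos[i] for i in sorted(idx)]
    true_kinase = {ex.peptide.sequence: ex.kinase_id for ex in test_pos}
    substrates = sorted(true_kinase)
    families = sorted({k.family for k in world.kinases})
    groups = sorted({k.group for k in world.kinases})
    return hit_at_1_from_model(model, substrates, true_kinase,
                               world.kinases, families, groups)


def attribution_study(model: MultitaskModel, examples: list[PairExample],
                      world: SyntheticWorld, peptides_per_kinase: int = 3,
                      kinase_block: int = 8, seed: int = 0
                      ) -> tuple[dict[str, list[AttributionVector]], float]:
    """Partition-Shapley attributions for true-positive pairs of every
    kinase, plus the planted-determinant recovery rate."""
    kinase_seq = {k.kinase_id: k.domain_sequence for k in world.kinases}
    explainer = PartitionExplainer(model)
    rng = np.random.default_rng(seed)
    by_kinase: dict[str, list[PairExample]] = {}
    for ex in examples:
        if ex.tier == POSITIVE:
            by_kinase.setdefault(ex.kinase_id, []).append(ex)
    attrs: dict[str, list[AttributionVector]] = {}
    for kid in sorted(by_kinase):
        pool = by_kinase[kid]
        take = min(peptides_per_kinase, len(pool))
        idx = rng.choice(len(pool), size=take, replace=False)
        attrs[kid] = [
            explainer.explain(pool[i].peptide.sequence, kinase_seq[kid],
                              kinase_block=kinase_block, kinase_id=kid)
            for i in idx]
    offsets = {kid: world.determinant_offsets(kid) for kid in attrs}
    return attrs, motif_recovery_rate(attrs, offsets)


def bimodal_decomposition(model: MultitaskModel,
                          examples: list[PairExample],
                          world: SyntheticWorld, kinase_id: str,
                          max_pairs: int = 30, kinase_block: int = 8,
                          seed: int = 0):
    """Motif decomposition for one kinase's true positives."""
    kinase_seq = {k.kinase_id: k.domain_sequence for k in world.kinases}
    pos = [ex for ex in examples
           if ex.tier == POSITIVE and ex.kinase_id == kinase_id]
    if not pos:
        raise ValueError(f"no positive pairs for {kinase_id}")
    rng = np.random.default_rng(seed)
    if len(pos) > max_pairs:
        idx = rng.choice(len(pos), size=max_pairs, replace=False)
        pos = [pos[i] for i in sorted(idx)]
    explainer = PartitionExplainer(model)
    attrs = [explainer.explain(ex.peptide.sequence, kinase_seq[kinase_id],
                               kinase_block=kinase_block,
                               kinase_id=kinase_id) for ex in pos]
    return motif_decomposition(kinase_id, attrs)
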