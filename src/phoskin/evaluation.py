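"""Benchmark suite: threshold-free discrimination metrics, easy-negative
false-positive rate, substrate-centric Hit@1 with macro-averaging, and the
held-out-kinase zero-shot ablation protocol.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

from .curation import (HARD_NEGATIVE, POSITIVE, PairExample, split_of)
from .model import ModelConfig, MultitaskModel
from .synthetic import KinaseRecord
from .training import TrainConfig, pretrain_mlm, train

logger = logging.getLogger(__name__)

VARIANTS = ("random_init", "pretrained", "pretrained_multitask")


@dataclass
class MetricsReport:
    auc_roc: float = float("nan")
    auc_prc: float = float("nan")
    accuracy: float = float("nan")
    fpr_easy: float = float("nan")
    hit1_group: float = float("nan")
    hit1_family: float = float("nan")
    n_examples: dict[str, int] = field(default_factory=dict)


def discrimination_metrics(scores, labels) -> dict[str, float]:
    """AUC ROC (rank statistic, mid-rank ties), AUC PRC (step-interpolated
    precision-recall), and accuracy at threshold 0.5."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")
    return {
        "auc_roc": float(roc_auc_score(labels, scores)),
        "auc_prc": float(average_precision_score(labels, scores)),
        "accuracy": float(np.mean((scores >= 0.5).astype(int) == labels)),
    }


def easy_negative_fpr(scores_on_easy_negatives, threshold: float = 0.5
                      ) -> float:
    """Fraction of easy-negative scores at or above the threshold."""
    scores = np.asarray(scores_on_easy_negatives, dtype=float)
    if scores.size == 0:
        raise ValueError("no easy-negative scores given")
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0, 1]")
    return float(np.mean(scores >= threshold))


def hit_at_1(scores_by_substrate: dict[str, dict[str, float]],
             true_kinase: dict[str, str],
             level_label: dict[str, str],
             level_classes: list[str]) -> tuple[dict[str, float], float]:
    """Substrate-centric top-1 evaluation at one label level.

    For each substrate, all candidate kinases are ranked by score (rank-1
    ties broken deterministically by kinase id, and logged); a hit iff the
    top kinase's level label equals the true kinase's.  Per-class accuracy
    is computed over substrates whose true kinase lies in that class; the
    macro-average is the unweighted mean over `level_classes`.
    """
    hits: dict[str, list[int]] = {c: [] for c in level_classes}
    for sub, cand in scores_by_substrate.items():
        tk = true_kinase[sub]
        cls = level_label[tk]
        if cls not in hits:
            continue
        ranked = sorted(cand.items(), key=lambda kv: (-kv[1], kv[0]))
        if len(ranked) > 1 and ranked[0][1] == ranked[1][1]:
            logger.info("rank-1 tie for substrate %s broken by kinase id",
                        sub)
        hits[cls].append(int(level_label[ranked[0][0]] == cls))
    per_class = {c: float(np.mean(v)) for c, v in hits.items() if v}
    macro = float(np.mean(list(per_class.values()))) if per_class \
        else float("nan")
    return per_class, macro


def hit_at_1_from_model(model: MultitaskModel, substrates: list[str],
                        true_kinase: dict[str, str],
                        kinases: list[KinaseRecord],
                        family_classes: list[str],
                        group_classes: list[str]
                        ) -> dict[str, object]:
    """Score every substrate against every kinase, then combine family- and
    group-level Hit@1 into one unweighted macro over all listed classes."""
    scores: dict[str, dict[str, float]] = {}
    kin_list = [(k.kinase_id, k.domain_sequence) for k in kinases]
    for sub in substrates:
        probs = model.predict_pairs([(sub, seq) for _, seq in kin_list])
        scores[sub] = {kid: float(p) for (kid, _), p in zip(kin_list, probs)}
    fam_label = {k.kinase_id: k.family for k in kinases}
    grp_label = {k.kinase_id: k.group for k in kinases}
    fam_acc, _ = hit_at_1(scores, true_kinase, fam_label, family_classes)
    grp_acc, _ = hit_at_1(scores, true_kinase, grp_label, group_classes)
    all_acc = list(fam_acc.values()) + list(grp_acc.values())
    return {"family": fam_acc, "group": grp_acc,
            "hit1_family": float(np.mean(list(fam_acc.values())))
            if fam_acc else float("nan"),
            "hit1_group": float(np.mean(list(grp_acc.values())))
            if grp_acc else float("nan"),
            "macro": float(np.mean(all_acc)) if all_acc else float("nan")}


# ---------------------------------------------------------------------------
# zero-shot ablation
# ---------------------------------------------------------------------------

def _score_examples(model: MultitaskModel, examples: list[PairExample],
                    kinase_seq: dict[str, str]) -> tuple[np.ndarray,
                                                         np.ndarray]:
    pairs = [(ex.peptide.sequence, kinase_seq[ex.kinase_id])
             for ex in examples]
    labels = np.array([ex.label for ex in examples])
    return model.predict_pairs(pairs), labels


def zero_shot_protocol(kinases: list[KinaseRecord],
                       dataset: list[PairExample],
                       mlm_corpus: list[str],
                       model_config: ModelConfig,
                       train_config: TrainConfig,
                       holdout_fraction: float = 0.10,
                       variants: tuple[str, ...] = VARIANTS,
                       pretrain_steps: int = 150,
                       pretrain_lr: float = 1e-3,
                       seed: int = 0,
                       strict_families: bool = False) -> dict:
    """Hold out ~`holdout_fraction` of kinases with all their pairs (Test
    set 2); carve an equally sized slice of the remaining pool (Test set
    1); train each initialization variant on the reduced training set and
    report AUC ROC / AUC PRC on both test sets.
    """
    if not 0.0 < holdout_fraction < 0.5:
        raise ValueError("holdout_fraction must be in (0, 0.5)")
    bad = set(variants) - set(VARIANTS)
    if bad:
        raise ValueError(f"unknown variants: {sorted(bad)}")
    rng = np.random.default_rng(seed)
    kin_ids = sorted(k.kinase_id for k in kinases)
    n_hold = int(math.floor(holdout_fraction * len(kin_ids)))
    if n_hold == 0:
        raise ValueError("holdout fraction leaves no held-out kinase")
    held = set(rng.choice(kin_ids, size=n_hold, replace=False).tolist())
    if strict_families:
        fam_of = {k.kinase_id: k.family for k in kinases}
        remaining = {fam_of[k] for k in kin_ids if k not in held}
        lost = {fam_of[k] for k in held} - remaining
        if lost:
            raise ValueError(f"holdout empties families {sorted(lost)}")

    scored = [ex for ex in dataset if ex.tier in (POSITIVE, HARD_NEGATIVE)]
    test2 = [ex for ex in scored if ex.kinase_id in held]
    if not any(ex.label == 1 for ex in test2) or \
            not any(ex.label == 0 for ex in test2):
        raise ValueError("held-out pairs do not contain both classes")
    pool = [ex for ex in dataset if ex.kinase_id not in held]
    train_pool = [ex for ex in pool if ex.split == "train"]
    # Test set 1: a random slice of the training pool, same size as Test 2
    scored_train = [i for i, ex in enumerate(train_pool)
                    if ex.tier in (POSITIVE, HARD_NEGATIVE)]
    n_t1 = min(len(test2), len(scored_train))
    t1_idx = set(rng.choice(scored_train, size=n_t1, replace=False).tolist())
    test1 = [train_pool[i] for i in sorted(t1_idx)]
    reduced_train = [ex for i, ex in enumerate(train_pool)
                     if i not in t1_idx]
    kinase_seq = {k.kinase_id: k.domain_sequence for k in kinases}
    train_kin = [k for k in kinases if k.kinase_id not in held]

    report: dict = {"held_out_kinases": sorted(held),
                    "n_test1": len(test1), "n_test2": len(test2),
                    "variants": {}}
    for v_i, variant in enumerate(variants):
        cfg = ModelConfig(**{**model_config.__dict__,
                             "seed": model_config.seed + 101 * v_i})
        model = MultitaskModel(cfg)
        if variant in ("pretrained", "pretrained_multitask"):
            pretrain_mlm(model, mlm_corpus, steps=pretrain_steps,
                         lr_init=pretrain_lr, seed=seed + 7)
            model.config.init = "pretrained_checkpoint"
        tcfg = TrainConfig(**{**train_config.__dict__,
                              "task_probability":
                              train_config.task_probability
                              if variant == "pretrained_multitask" else 1.0,
                              "seed": train_config.seed + v_i})
        train(model, reduced_train, train_kin, mlm_corpus, tcfg,
              checkpoint_dir=None)
        entry = {}
        for name, test in (("test1", test1), ("test2", test2)):
            scores, labels = _score_examples(model, test, kinase_seq)
            m = discrimination_metrics(scores, labels)
            entry[name] = {"auc_roc": m["auc_roc"], "auc_prc": m["auc_prc"]}
        report["variants"][variant] = entry
    return report
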