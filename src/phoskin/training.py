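"""Multitask training loop.

A task manager draws, per batch, between masked-language modeling on the
kinase corpus and kinase-peptide classification on the curated dataset.
Both objectives use cross-entropy, a shared linear learning-rate decay to
zero, and AdamW.  Checkpoints (including the step-0 pre-fine-tuning state)
are saved for the interpretability module.

Step accounting: `epochs` counts passes over the classification training
split; MLM batches drawn by the task manager are additional steps, so all
initialization variants in an ablation see identical classification
exposure.  The task sequence is drawn up front from the seed, which makes
the total step count (and hence the LR schedule) deterministic.
"""
from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from . import nn
from .augment import AugmentConfig, augment_kinase_sequence
from .curation import PairExample, split_of
from .model import MultitaskModel, mlm_corrupt
from .synthetic import KinaseRecord
from .vocab import SPECIALS, pad_batch, tokenize_pair, tokenize_single

MLM = "mlm"
CLASSIFICATION = "classification"


@dataclass
class TrainConfig:
    lr_init: float = 2e-5
    epochs: int = 3
    task_probability: float = 0.5   # P(batch is classification)
    batch_size: int = 16
    grad_accum_steps: int = 1
    checkpoint_every: int = 100
    mlm_mask_prob: float = 0.15
    weight_decay: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lr_init <= 0:
            raise ValueError("lr_init must be positive")
        if not 0.0 <= self.task_probability <= 1.0:
            raise ValueError("task_probability must be in [0, 1]")


def task_manager(step: int, rng: np.random.Generator,
                 task_probability: float) -> str:
    """Bernoulli draw per batch between the two objectives."""
    if not 0.0 <= task_probability <= 1.0:
        raise ValueError("task_probability must be in [0, 1]")
    return CLASSIFICATION if rng.random() < task_probability else MLM


def lr_schedule(step: int, total_steps: int, lr_init: float) -> float:
    """Linear decay from lr_init at step 0 to 0 at total_steps."""
    if step > total_steps:
        warnings.warn(f"step {step} beyond schedule end {total_steps}; "
                      "clamping learning rate to 0")
        return 0.0
    return lr_init * (1.0 - step / total_steps)


def draw_task_sequence(n_class_steps: int, task_probability: float,
                       rng: np.random.Generator) -> list[str]:
    """Draw tasks until the classification budget is spent."""
    if task_probability <= 0.0:
        return []
    tasks: list[str] = []
    done = 0
    while done < n_class_steps:
        t = task_manager(len(tasks), rng, task_probability)
        tasks.append(t)
        if t == CLASSIFICATION:
            done += 1
    return tasks


def _classification_loss(model: MultitaskModel, batch: list[PairExample],
                         kinase_seq: dict[str, str],
                         augment: AugmentConfig | None,
                         rng: np.random.Generator) -> nn.Tensor:
    toks, labels = [], []
    for ex in batch:
        kin = kinase_seq[ex.kinase_id]
        if augment is not None:
            rec = KinaseRecord(ex.kinase_id, kin, "", "", "")
            kin = augment_kinase_sequence(rec, augment, rng)
        toks.append(tokenize_pair(ex.peptide.sequence, kin, model.vocab,
                                  require_st_center=False).token_ids)
        labels.append(ex.label)
    ids, mask = pad_batch(toks, model.vocab)
    h = model.encode(ids, mask, training=True)
    logits = model.classify_logits(h, ids, mask)
    return nn.cross_entropy_logits(logits, np.asarray(labels))


def _mlm_loss(model: MultitaskModel, seqs: list[str], mask_prob: float,
              rng: np.random.Generator) -> nn.Tensor:
    toks = [tokenize_single(s, model.vocab) for s in seqs]
    ids, mask = pad_batch(toks, model.vocab)
    corrupted, chosen = mlm_corrupt(ids, model.vocab, rng, mask_prob)
    if not chosen.any():        # degenerate draw; force one mask
        pos = np.argwhere(ids >= len(SPECIALS))[0]
        chosen[pos[0], pos[1]] = True
        corrupted[pos[0], pos[1]] = model.vocab.mask_id
    h = model.encode(corrupted, mask, training=True)
    logits = model.mlm_logits(h)
    flat = logits.reshape(-1, logits.shape[-1])
    sel = flat[np.flatnonzero(chosen.reshape(-1))]
    return nn.cross_entropy_logits(sel, ids.reshape(-1)[chosen.reshape(-1)])


def train(model: MultitaskModel, dataset: list[PairExample],
          kinases: list[KinaseRecord], mlm_corpus: list[str],
          train_config: TrainConfig | None = None,
          augment_config: AugmentConfig | None = None,
          checkpoint_dir: str | Path | None = None
          ) -> tuple[list[Path], list[dict]]:
    """Run the multitask loop; returns (checkpoint paths, loss history)."""
    cfg = train_config or TrainConfig()
    rng = np.random.default_rng(cfg.seed)
    train_split = split_of(dataset, "train")
    if not train_split:
        raise ValueError("dataset has no train split")
    if cfg.task_probability < 1.0 and not mlm_corpus:
        raise ValueError("MLM corpus is empty but task_probability < 1")
    kinase_seq = {k.kinase_id: k.domain_sequence for k in kinases}

    n_batches = math.ceil(len(train_split) / cfg.batch_size)
    n_class_steps = cfg.epochs * n_batches
    if cfg.task_probability > 0.0:
        tasks = draw_task_sequence(n_class_steps, cfg.task_probability, rng)
    else:
        tasks = [MLM] * n_class_steps
    total_steps = len(tasks)

    opt = nn.AdamW(model.parameters(), lr=cfg.lr_init,
                   weight_decay=cfg.weight_decay)
    ckpt_paths: list[Path] = []
    history: list[dict] = []

    def save_ckpt(step: int) -> None:
        if checkpoint_dir is None:
            return
        path = Path(checkpoint_dir) / f"ckpt_{step:06d}"
        model.save(path)
        ckpt_paths.append(path)

    save_ckpt(0)    # the pre-fine-tuning state

    order = rng.permutation(len(train_split))
    class_cursor = 0
    mlm_cursor = 0
    epoch = 0
    for step, task in enumerate(tasks):
        lr = lr_schedule(step, total_steps, cfg.lr_init)
        opt.lr = lr
        opt.zero_grad()
        loss_val = 0.0
        for _ in range(cfg.grad_accum_steps):
            if task == CLASSIFICATION:
                lo = class_cursor * cfg.batch_size
                batch = [train_split[i]
                         for i in order[lo:lo + cfg.batch_size]]
                class_cursor += 1
                if class_cursor >= n_batches:
                    class_cursor = 0
                    epoch += 1
                    order = rng.permutation(len(train_split))
                loss = _classification_loss(model, batch, kinase_seq,
                                            augment_config, rng)
            else:
                seqs = [mlm_corpus[(mlm_cursor + i) % len(mlm_corpus)]
                        for i in range(cfg.batch_size)]
                mlm_cursor = (mlm_cursor + cfg.batch_size) % len(mlm_corpus)
                loss = _mlm_loss(model, seqs, cfg.mlm_mask_prob, rng)
            scaled = loss / cfg.grad_accum_steps
            scaled.backward()
            loss_val += float(loss.data) / cfg.grad_accum_steps
        if not np.isfinite(loss_val):
            snapshot = {"step": step, "task": task, "loss": loss_val,
                        "lr": lr, "epoch": epoch}
            raise RuntimeError(f"non-finite loss; diagnostics: {snapshot}")
        opt.step()
        history.append({"step": step, "task": task, "loss": loss_val,
                        "lr": lr, "epoch": epoch})
        if cfg.checkpoint_every > 0 and (step + 1) % cfg.checkpoint_every == 0:
            save_ckpt(step + 1)

    if checkpoint_dir is not None:
        if not ckpt_paths or ckpt_paths[-1].name != f"ckpt_{total_steps:06d}":
            save_ckpt(total_steps)
        manifest = {"train_config": asdict(cfg), "total_steps": total_steps,
                    "checkpoints": [p.name for p in ckpt_paths]}
        (Path(checkpoint_dir) / "training_manifest.json").write_text(
            json.dumps(manifest, indent=2))
    return ckpt_paths, history


def pretrain_mlm(model: MultitaskModel, corpus: list[str], steps: int,
                 lr_init: float = 1e-3, batch_size: int = 8,
                 mask_prob: float = 0.15, seed: int = 0) -> list[float]:
    """MLM-only pretraining on a kinase-domain corpus; returns losses."""
    if not corpus:
        raise ValueError("corpus must be non-empty")
    rng = np.random.default_rng(seed)
    opt = nn.AdamW(model.parameters(), lr=lr_init)
    losses = []
    for step in range(steps):
        opt.lr = lr_schedule(step, steps, lr_init)
        idx = rng.integers(0, len(corpus), size=batch_size)
        loss = _mlm_loss(model, [corpus[i] for i in idx], mask_prob, rng)
        opt.zero_grad()
        loss.backward()
        losses.append(float(loss.data))
        opt.step()
    return losses


def write_loss_history(history: list[dict], path: str | Path) -> None:
    import pandas as pd
    pd.DataFrame(history).to_csv(path, sep="\t", index=False)
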