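"""Training-time augmentations: domain-boundary shifting, random and
Markov (span) masking, and multi-level negative sampling.

Peptide identity is never augmented — mutating the substrate would corrupt
its label.  Masked residues are written as ``#``, which the tokenizer maps
to the ``<mask>`` token.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .curation import POSITIVE, PairExample
from .synthetic import KinaseRecord

logger = logging.getLogger(__name__)

MASK_CHAR = "#"

LEVELS = ("same_family", "same_group", "random")


@dataclass
class AugmentConfig:
    max_boundary_shift: int = 10
    random_mask_prob: float = 0.10
    markov_enter_prob: float = 0.03
    markov_stay_prob: float = 0.80
    negative_level_weights: tuple[float, float, float] = (1.0, 1.0, 1.0)
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.random_mask_prob, self.markov_enter_prob,
                  self.markov_stay_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must be in [0, 1]")
        w = np.asarray(self.negative_level_weights, dtype=float)
        if (w < 0).any() or w.sum() == 0:
            raise ValueError("level weights must be nonnegative, not all 0")


def shift_domain_boundary(source_seq: str, domain_start: int, domain_end: int,
                          max_shift: int, rng: np.random.Generator,
                          max_retries: int = 20) -> str:
    """Independently offset both domain bounds by uniform integers in
    [-max_shift, +max_shift], clipped to the source sequence."""
    if not 0 <= domain_start < domain_end <= len(source_seq):
        raise ValueError("invalid domain bounds")
    for _ in range(max_retries + 1):
        s = int(np.clip(domain_start + rng.integers(-max_shift,
                                                    max_shift + 1),
                        0, len(source_seq)))
        e = int(np.clip(domain_end + rng.integers(-max_shift, max_shift + 1),
                        0, len(source_seq)))
        if e - s >= 1:
            return source_seq[s:e]
    raise RuntimeError("could not draw non-inverted domain bounds "
                       f"after {max_retries} retries")


def random_mask(seq: str, p: float, rng: np.random.Generator) -> str:
    """Mask each position independently with probability p."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must be in [0, 1]")
    hits = rng.random(len(seq)) < p
    return "".join(MASK_CHAR if h else c for c, h in zip(seq, hits))


def markov_mask(seq: str, enter_prob: float, stay_prob: float,
                rng: np.random.Generator) -> str:
    """Two-state chain along the sequence: unmasked -> masked with
    `enter_prob`, masked -> masked with `stay_prob`.  Masked runs are
    geometric with mean 1/(1 - stay_prob); the long-run masked fraction is
    enter/(enter + 1 - stay)."""
    if not (0.0 <= enter_prob < 1.0 and 0.0 <= stay_prob < 1.0):
        raise ValueError("probabilities must be in [0, 1)")
    draws = rng.random(len(seq))
    out = []
    masked = False
    for c, u in zip(seq, draws):
        masked = u < (stay_prob if masked else enter_prob)
        out.append(MASK_CHAR if masked else c)
    return "".join(out)


@dataclass
class PairIndex:
    """Index over a labeled dataset for multi-level negative sampling."""
    examples: list[PairExample]
    kinases: list[KinaseRecord]
    positive_keys: set[tuple[str, str]] = field(init=False)
    family_of: dict[str, str] = field(init=False)
    group_of: dict[str, str] = field(init=False)
    _negatives: list[PairExample] = field(init=False)

    def __post_init__(self) -> None:
        self.positive_keys = {e.key for e in self.examples
                              if e.tier == POSITIVE}
        self.family_of = {k.kinase_id: k.family for k in self.kinases}
        self.group_of = {k.kinase_id: k.group for k in self.kinases}
        self._negatives = [e for e in self.examples if e.tier != POSITIVE]

    def candidates(self, anchor_kinase: str, level: str
                   ) -> list[PairExample]:
        if level == "random":
            return self._negatives
        if level == "same_family":
            fam = self.family_of.get(anchor_kinase)
            return [e for e in self._negatives
                    if self.family_of.get(e.kinase_id) == fam]
        if level == "same_group":
            grp = self.group_of.get(anchor_kinase)
            return [e for e in self._negatives
                    if self.group_of.get(e.kinase_id) == grp]
        raise ValueError(f"unknown level {level!r}")


def sample_negative_multilevel(anchor_pair: PairExample, index: PairIndex,
                               level_weights, rng: np.random.Generator
                               ) -> tuple[PairExample, str]:
    """Choose a relatedness level by the weights, then sample a negative
    whose kinase relates to the anchor's at that level.  Falls back to
    "random" (with a log line) when a level has no candidates.  Returns
    (example, level actually used)."""
    w = np.asarray(level_weights, dtype=float)
    w = w / w.sum()
    level = LEVELS[rng.choice(len(LEVELS), p=w)]
    cands = index.candidates(anchor_pair.kinase_id, level)
    if not cands:
        logger.debug("no %s negatives for anchor %s; falling back to random",
                     level, anchor_pair.kinase_id)
        level = "random"
        cands = index.candidates(anchor_pair.kinase_id, level)
        if not cands:
            raise ValueError("dataset contains no negative examples")
    ex = cands[rng.integers(len(cands))]
    assert ex.key not in index.positive_keys
    return ex, level


def augment_kinase_sequence(kin: KinaseRecord, config: AugmentConfig,
                            rng: np.random.Generator) -> str:
    """Boundary shift + one of the masking schemes, as used per batch."""
    seq = kin.domain_sequence
    if config.max_boundary_shift > 0:
        seq = shift_domain_boundary(seq, 0, len(seq),
                                    config.max_boundary_shift, rng)
    if rng.random() < 0.5:
        return random_mask(seq, config.random_mask_prob, rng)
    return markov_mask(seq, config.markov_enter_prob,
                       config.markov_stay_prob, rng)
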