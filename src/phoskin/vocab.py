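"""Amino-acid vocabulary and the paired-sequence tokenizer.

A kinase-substrate pair is laid out as::

    <cls> p1 ... p15 <eos> k1 ... kL <eos>

so the candidate phosphosite (the 8th peptide residue) always sits at the
9th token.  Single sequences (used for masked-language-model training) are
``<cls> r1 ... rL <eos>``.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
SPECIALS = ("<cls>", "<pad>", "<eos>", "<unk>", "<mask>")

PEPTIDE_LEN = 15
#: 0-based token index of the phosphosite (9th token, 1-based).
PHOSPHOSITE_INDEX = 8


class Vocabulary:
    """Fixed residue + special-symbol vocabulary with stable integer ids."""

    def __init__(self) -> None:
        self._tokens = list(SPECIALS) + list(AMINO_ACIDS)
        self._ids = {t: i for i, t in enumerate(self._tokens)}
        self.cls_id = self._ids["<cls>"]
        self.pad_id = self._ids["<pad>"]
        self.eos_id = self._ids["<eos>"]
        self.unk_id = self._ids["<unk>"]
        self.mask_id = self._ids["<mask>"]

    def __len__(self) -> int:
        return len(self._tokens)

    def encode_residue(self, aa: str) -> int:
        if aa == "#":          # augmentation writes masked residues as '#'
            return self.mask_id
        return self._ids.get(aa, self.unk_id)

    def encode_sequence(self, seq: str) -> np.ndarray:
        return np.array([self.encode_residue(a) for a in seq], dtype=np.int64)

    def decode(self, ids) -> str:
        return "".join(self._tokens[i] for i in np.asarray(ids).ravel())

    @property
    def residue_ids(self) -> np.ndarray:
        return np.arange(len(SPECIALS), len(self._tokens), dtype=np.int64)

    def to_json(self) -> str:
        return json.dumps(self._ids, indent=0)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())


@dataclass
class TokenizedPair:
    """Token ids for one kinase-peptide pair, with span bookkeeping."""

    token_ids: np.ndarray
    peptide_span: tuple[int, int]      # 0-based half-open [start, stop)
    kinase_span: tuple[int, int]
    phosphosite_index: int = PHOSPHOSITE_INDEX
    attention_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.attention_mask is None:
            self.attention_mask = np.ones(len(self.token_ids), dtype=np.int64)


def tokenize_pair(peptide: str, kinase_domain: str, vocab: Vocabulary,
                  require_st_center: bool = True) -> TokenizedPair:
    """Tokenize a 15-mer peptide plus kinase domain into the paired layout."""
    if len(peptide) != PEPTIDE_LEN:
        raise ValueError(f"peptide must be length {PEPTIDE_LEN}, "
                         f"got {len(peptide)}")
    if len(kinase_domain) == 0:
        raise ValueError("kinase domain must be non-empty")
    if require_st_center and peptide[7] not in "ST":
        raise ValueError(f"central residue must be S or T, got {peptide[7]!r}")
    ids = np.concatenate([
        [vocab.cls_id],
        vocab.encode_sequence(peptide),
        [vocab.eos_id],
        vocab.encode_sequence(kinase_domain),
        [vocab.eos_id],
    ]).astype(np.int64)
    L = len(kinase_domain)
    return TokenizedPair(token_ids=ids,
                         peptide_span=(1, 1 + PEPTIDE_LEN),
                         kinase_span=(PEPTIDE_LEN + 2, PEPTIDE_LEN + 2 + L))


def tokenize_single(seq: str, vocab: Vocabulary) -> np.ndarray:
    """``<cls> residues <eos>`` layout for single-sequence (MLM) inputs."""
    if len(seq) == 0:
        raise ValueError("sequence must be non-empty")
    return np.concatenate([[vocab.cls_id], vocab.encode_sequence(seq),
                           [vocab.eos_id]]).astype(np.int64)


def pad_batch(id_arrays: list[np.ndarray], vocab: Vocabulary
              ) -> tuple[np.ndarray, np.ndarray]:
    """Right-pad variable-length token arrays; returns (ids, mask)."""
    n = len(id_arrays)
    width = max(len(a) for a in id_arrays)
    ids = np.full((n, width), vocab.pad_id, dtype=np.int64)
    mask = np.zeros((n, width), dtype=np.int64)
    for i, a in enumerate(id_arrays):
        ids[i, : len(a)] = a
        mask[i, : len(a)] = 1
    return ids, mask
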