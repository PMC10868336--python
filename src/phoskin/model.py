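"""The multitask network: shared encoder, MLM decoder, cross-attention
pair classifier anchored on the phosphosite token.

The shared encoder is a pre-norm transformer over the tokenized input.  For
masked-language modeling a linear decoder scores every position over the
vocabulary.  For pair classification, peptide- and kinase-position
embeddings are separated and passed through a single multi-head
cross-attention layer (peptide positions as queries, kinase positions as
keys/values, so attention-updated vectors remain indexed by peptide
positions); the updated phosphosite vector feeds a binary linear layer and
a two-class softmax.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field
from pathlib import Path

import numpy as np

from . import nn
from .nn import Tensor
from .vocab import (PEPTIDE_LEN, PHOSPHOSITE_INDEX, SPECIALS, Vocabulary,
                    pad_batch, tokenize_pair)

_NEG_BIAS = -1e9


@dataclass
class ModelConfig:
    d_model: int = 64
    n_layers: int = 2
    n_heads: int = 4
    d_ff: int = 128
    head_heads: int = 4            # heads in the classifier cross-attention
    max_len: int = 512
    dropout: float = 0.0
    init: str = "random"           # random | pretrained_checkpoint
    reverse_cross_attention: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.d_model % self.n_heads:
            raise ValueError("d_model must be divisible by n_heads")
        if self.d_model % self.head_heads:
            raise ValueError("d_model must be divisible by head_heads")


class MultitaskModel(nn.Module):
    """Shared encoder + MLM decoder + phosphosite pair classifier."""

    def __init__(self, config: ModelConfig, vocab: Vocabulary | None = None):
        self.config = config
        self.vocab = vocab or Vocabulary()
        rng = np.random.default_rng(config.seed)
        V, D = len(self.vocab), config.d_model
        self.tok_emb = nn.Embedding(V, D, rng)
        self.pos_emb = nn.Embedding(config.max_len, D, rng)
        self.layers = [nn.EncoderLayer(D, config.n_heads, config.d_ff, rng)
                       for _ in range(config.n_layers)]
        self.ln_final = nn.LayerNorm(D)
        self.mlm_head = nn.Linear(D, V, rng)
        # classifier: pre-norm residual cross-attention block + binary layer
        self.cls_ln_q = nn.LayerNorm(D)
        self.cls_ln_kv = nn.LayerNorm(D)
        self.cls_attn = nn.MultiHeadAttention(D, config.head_heads, rng)
        self.cls_out = nn.Linear(D, 2, rng)
        self._train_rng = np.random.default_rng(config.seed + 1)

    # ------------------------------------------------------------------
    def encode(self, token_ids: np.ndarray, attention_mask: np.ndarray
               | None = None, training: bool = False) -> Tensor:
        """Per-token embeddings, shape (batch, n_tokens, d_model)."""
        token_ids = np.atleast_2d(np.asarray(token_ids, dtype=np.int64))
        B, N = token_ids.shape
        if N > self.config.max_len:
            raise ValueError(
                f"input length {N} exceeds max_len {self.config.max_len}; "
                "shorten the kinase domain or raise max_len — inputs are "
                "never silently truncated")
        if attention_mask is None:
            attention_mask = np.ones_like(token_ids)
        pad_bias = np.where(attention_mask[:, None, None, :] == 1,
                            0.0, _NEG_BIAS).astype(np.float32)
        x = self.tok_emb(token_ids) + self.pos_emb(
            np.broadcast_to(np.arange(N), (B, N)))
        for layer in self.layers:
            x = layer(x, pad_bias)
            if training and self.config.dropout > 0:
                x = nn.dropout(x, self.config.dropout, self._train_rng, True)
        return self.ln_final(x)

    def mlm_logits(self, embeddings: Tensor) -> Tensor:
        """Vocabulary scores per position, shape (..., n_tokens, vocab)."""
        return self.mlm_head(embeddings)

    def classify_logits(self, embeddings: Tensor, token_ids: np.ndarray,
                        attention_mask: np.ndarray | None = None) -> Tensor:
        """Two-class logits for paired-layout inputs, shape (batch, 2)."""
        token_ids = np.atleast_2d(token_ids)
        B, N = token_ids.shape
        if embeddings.shape[:2] != (B, N):
            raise ValueError("embeddings inconsistent with token ids")
        if N < PEPTIDE_LEN + 3:
            raise ValueError("input too short for the paired layout")
        pep = embeddings[:, 1:1 + PEPTIDE_LEN, :]
        kin = embeddings[:, PEPTIDE_LEN + 2:, :]
        kin_ids = token_ids[:, PEPTIDE_LEN + 2:]
        valid = (kin_ids != self.vocab.pad_id) & (kin_ids != self.vocab.eos_id)
        if attention_mask is not None:
            valid &= attention_mask[:, PEPTIDE_LEN + 2:] == 1
        if not self.config.reverse_cross_attention:
            bias = np.where(valid[:, None, None, :], 0.0,
                            _NEG_BIAS).astype(np.float32)
            q = pep + self.cls_attn(self.cls_ln_q(pep),
                                    self.cls_ln_kv(kin), bias)
            anchor = q[:, PHOSPHOSITE_INDEX - 1, :]   # phosphosite position
        else:
            # comparison mode: kinase positions query the peptide; the
            # phosphosite anchor is replaced by a masked mean over kinase
            # positions since no peptide-indexed output exists.
            q = kin + self.cls_attn(self.cls_ln_q(kin),
                                    self.cls_ln_kv(pep), None)
            w = (valid / np.maximum(valid.sum(axis=1, keepdims=True), 1)
                 ).astype(np.float32)
            anchor = (q * Tensor(w[:, :, None])).sum(axis=1)
        return self.cls_out(anchor)

    # ------------------------------------------------------------------
    def predict_proba(self, token_ids: np.ndarray,
                      attention_mask: np.ndarray | None = None) -> np.ndarray:
        """Positive-class probability per pair (evaluation mode)."""
        h = self.encode(token_ids, attention_mask, training=False)
        logits = self.classify_logits(h, token_ids, attention_mask).data
        z = logits - logits.max(axis=-1, keepdims=True)
        e = np.exp(z)
        p = e / e.sum(axis=-1, keepdims=True)
        return p[:, 1]

    def predict_pairs(self, pairs: list[tuple[str, str]],
                      batch_size: int = 64) -> np.ndarray:
        """Score (peptide, kinase_domain) string pairs."""
        out = np.empty(len(pairs))
        for lo in range(0, len(pairs), batch_size):
            chunk = pairs[lo:lo + batch_size]
            toks = [tokenize_pair(p, k, self.vocab,
                                  require_st_center=False).token_ids
                    for p, k in chunk]
            ids, mask = pad_batch(toks, self.vocab)
            out[lo:lo + len(chunk)] = self.predict_proba(ids, mask)
        return out

    def phosphosite_embeddings(self, token_ids: np.ndarray,
                               attention_mask: np.ndarray | None = None
                               ) -> np.ndarray:
        """Encoder output at the phosphosite token, shape (batch, d_model)."""
        h = self.encode(token_ids, attention_mask, training=False)
        return h.data[:, PHOSPHOSITE_INDEX, :].copy()

    # ------------------------------------------------------------------
    def save(self, path: str | Path) -> None:
        """Checkpoint = JSON header (config + vocab) and an .npz of weights."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        (path / "config.json").write_text(json.dumps(
            {"model_config": asdict(self.config),
             "vocab": json.loads(self.vocab.to_json())}, indent=2))
        np.savez(path / "weights.npz", **self.state_dict())

    @classmethod
    def load(cls, path: str | Path) -> "MultitaskModel":
        path = Path(path)
        header = json.loads((path / "config.json").read_text())
        model = cls(ModelConfig(**header["model_config"]))
        vocab_ids = {t: i for i, t in
                     enumerate(sorted(header["vocab"],
                                      key=header["vocab"].get))}
        if vocab_ids != header["vocab"]:
            raise ValueError("checkpoint vocabulary is not contiguous")
        with np.load(path / "weights.npz") as z:
            model.load_state_dict({k: z[k] for k in z.files})
        return model


def mlm_corrupt(token_ids: np.ndarray, vocab: Vocabulary,
                rng: np.random.Generator, mask_prob: float = 0.15
                ) -> tuple[np.ndarray, np.ndarray]:
    """Mask residue positions for the MLM objective.

    A fraction ``mask_prob`` of residue positions (never special tokens) is
    selected and replaced by ``<mask>``.  Returns the corrupted ids and a
    boolean array marking the selected positions (the prediction targets).
    """
    ids = np.array(token_ids, dtype=np.int64, copy=True)
    is_residue = ids >= len(SPECIALS)
    chosen = is_residue & (rng.random(ids.shape) < mask_prob)
    ids[chosen] = vocab.mask_id
    return ids, chosen
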