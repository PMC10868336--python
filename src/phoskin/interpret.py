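"""Explainability suite.

Four instruments for opening up the trained pair classifier:

* phosphosite-token embeddings per checkpoint, and a *joint* 2-D UMAP over
  all checkpoints (stack, project once, unstack) so that training
  trajectories share one coordinate frame;
* per-residue Shapley attributions from a partition (Owen-value)
  explainer: positions are organized in a partition tree whose peptide and
  kinase subtrees are kept separate, masking replaces a position's token
  with ``<mask>``, and the base value is the model output under full
  masking.  At every tree node exact Shapley values are computed over the
  node's children given the inherited context distribution, so the
  efficiency identity base + sum(attributions) = prediction holds to
  floating-point accuracy, and a flat root of singleton leaves reproduces
  exact Shapley values;
* descriptive polarity summaries of peptide-part vs kinase-part
  contributions;
* affinity-propagation decomposition of a kinase's true-positive
  attribution vectors into motif clusters, rendered as sequence logos.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from itertools import combinations

import numpy as np
import pandas as pd

from .model import MultitaskModel
from .synthetic import AA_INDEX, CENTER_ROW
from .vocab import PEPTIDE_LEN, PHOSPHOSITE_INDEX, pad_batch, tokenize_pair

__all__ = [
    "AttributionVector", "MotifCluster", "ProjectionSet", "PartitionNode",
    "extract_phosphosite_embeddings", "joint_projection",
    "build_pair_tree", "flat_tree", "balanced_tree", "owen_attributions",
    "exact_shapley", "shap_attributions",
    "attribution_polarity_summary", "motif_decomposition",
    "sequence_logo_matrix", "information_content", "motif_recovery_rate",
]

EFFICIENCY_TOL = 1e-4


# ---------------------------------------------------------------------------
# embeddings and projections
# ---------------------------------------------------------------------------

def extract_phosphosite_embeddings(model: MultitaskModel,
                                   pairs: list[tuple[str, str]],
                                   batch_size: int = 64) -> np.ndarray:
    """Encoder output at the phosphosite token for each (peptide, kinase)
    pair; rows align with the input order."""
    rows = []
    for lo in range(0, len(pairs), batch_size):
        chunk = pairs[lo:lo + batch_size]
        toks = [tokenize_pair(p, k, model.vocab,
                              require_st_center=False).token_ids
                for p, k in chunk]
        ids, mask = pad_batch(toks, model.vocab)
        rows.append(model.phosphosite_embeddings(ids, mask))
    return np.vstack(rows)


@dataclass
class ProjectionSet:
    coords: dict[str, np.ndarray]             # checkpoint tag -> (n, 2)
    annotations: pd.DataFrame | None = None   # central residue, groups, ...

    def to_frame(self) -> pd.DataFrame:
        frames = []
        for tag, xy in self.coords.items():
            df = pd.DataFrame(xy, columns=["x", "y"])
            df.insert(0, "checkpoint", tag)
            df.insert(1, "pair_index", np.arange(len(df)))
            if self.annotations is not None:
                df = pd.concat([df, self.annotations.reset_index(drop=True)],
                               axis=1)
            frames.append(df)
        return pd.concat(frames, ignore_index=True)


def joint_projection(per_checkpoint_embeddings: dict[str, np.ndarray],
                     seed: int = 0, n_neighbors: int = 15,
                     min_dist: float = 0.1,
                     annotations: pd.DataFrame | None = None
                     ) -> ProjectionSet:
    """Concatenate all checkpoints' phosphosite embeddings, reduce jointly
    to 2-D with UMAP (fixed seed), then unstack by checkpoint."""
    tags = list(per_checkpoint_embeddings)
    mats = [np.asarray(per_checkpoint_embeddings[t]) for t in tags]
    widths = {m.shape[1] for m in mats}
    counts = {m.shape[0] for m in mats}
    if len(widths) != 1 or len(counts) != 1:
        raise ValueError("all checkpoints must share row count and width")
    stacked = np.vstack(mats)
    if stacked.shape[0] <= n_neighbors:
        raise ValueError(
            f"{stacked.shape[0]} rows is too few for n_neighbors="
            f"{n_neighbors}; reduce n_neighbors")
    import umap
    reducer = umap.UMAP(n_components=2, n_neighbors=n_neighbors,
                        min_dist=min_dist, random_state=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")     # umap warns about random_state
        xy = reducer.fit_transform(stacked)
    n = mats[0].shape[0]
    coords = {t: xy[i * n:(i + 1) * n] for i, t in enumerate(tags)}
    return ProjectionSet(coords=coords, annotations=annotations)


# ---------------------------------------------------------------------------
# partition (Owen) Shapley explainer
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PartitionNode:
    """A node of the partition tree; leaves own one or more positions and
    split their credit equally among them."""
    positions: tuple[int, ...]
    children: tuple["PartitionNode", ...] = ()

    @property
    def is_leaf(self) -> bool:
        return not self.children


def balanced_tree(positions: list[int], leaf_size: int = 1) -> PartitionNode:
    """Balanced binary tree over the given positions; leaves hold at most
    `leaf_size` positions."""
    if len(positions) <= leaf_size:
        return PartitionNode(tuple(positions))
    mid = (len(positions) + 1) // 2
    left = balanced_tree(positions[:mid], leaf_size)
    right = balanced_tree(positions[mid:], leaf_size)
    return PartitionNode(tuple(positions), (left, right))


def flat_tree(n_positions: int) -> PartitionNode:
    """Root with singleton children: exact Shapley (exponential cost)."""
    leaves = tuple(PartitionNode((i,)) for i in range(n_positions))
    return PartitionNode(tuple(range(n_positions)), leaves)


def build_pair_tree(kinase_len: int, kinase_block: int = 1) -> PartitionNode:
    """Default tree: peptide and kinase subtrees kept separate so
    coalitions respect the biological segmentation.  Peptide positions
    (0..14) are singleton leaves; kinase positions are grouped into
    contiguous blocks of `kinase_block` residues to bound the number of
    model evaluations (credit within a block is split equally)."""
    pep = balanced_tree(list(range(PEPTIDE_LEN)), leaf_size=1)
    kin = balanced_tree(list(range(PEPTIDE_LEN, PEPTIDE_LEN + kinase_len)),
                        leaf_size=max(1, kinase_block))
    return PartitionNode(tuple(range(PEPTIDE_LEN + kinase_len)), (pep, kin))


@lru_cache(maxsize=None)
def _shapley_weight(s: int, k: int) -> float:
    return math.factorial(s) * math.factorial(k - 1 - s) / math.factorial(k)


def _recurse(node: PartitionNode, contexts: dict[frozenset, float],
             leaf_visit) -> None:
    """Shared traversal: model evaluations happen only at leaves.

    `contexts` maps an "on outside the node" position set to its weight;
    at each internal node the children are treated as players in an exact
    Shapley computation, and each child inherits the context distribution
    of the orders in which it is added.
    """
    if node.is_leaf:
        leaf_visit(node, contexts)
        return
    k = len(node.children)
    child_pos = [frozenset(c.positions) for c in node.children]
    for i, child in enumerate(node.children):
        others = [j for j in range(k) if j != i]
        child_ctx: dict[frozenset, float] = {}
        for O, w in contexts.items():
            for r in range(len(others) + 1):
                sw = _shapley_weight(r, k)
                for S in combinations(others, r):
                    U = O.union(*(child_pos[j] for j in S)) if S else O
                    child_ctx[U] = child_ctx.get(U, 0.0) + w * sw
        _recurse(child, child_ctx, leaf_visit)


def owen_attributions(value_fn, n_positions: int,
                      tree: PartitionNode | None = None
                      ) -> tuple[np.ndarray, float, float]:
    """Partition (Owen-value) attributions for an arbitrary set function.

    `value_fn` receives a list of coalitions (frozensets of positions that
    are ON) and returns one scalar per coalition.  Returns (phi, base,
    full) where base = value(empty), full = value(all positions) and
    base + phi.sum() = full up to floating point.  With a flat root of
    singleton children this is the exact Shapley value.
    """
    if tree is None:
        tree = balanced_tree(list(range(n_positions)))
    if set(tree.positions) != set(range(n_positions)):
        raise ValueError("tree does not cover positions 0..n-1")

    needed: set[frozenset] = set()

    def collect(leaf: PartitionNode, contexts: dict[frozenset, float]):
        P = frozenset(leaf.positions)
        for O in contexts:
            needed.add(O)
            needed.add(O | P)

    _recurse(tree, {frozenset(): 1.0}, collect)
    full = frozenset(range(n_positions))
    needed.update((frozenset(), full))
    order = list(needed)
    f = dict(zip(order, np.asarray(value_fn(order), dtype=float)))

    phi = np.zeros(n_positions)

    def credit(leaf: PartitionNode, contexts: dict[frozenset, float]):
        P = frozenset(leaf.positions)
        total = sum(w * (f[O | P] - f[O]) for O, w in contexts.items())
        phi[list(leaf.positions)] += total / len(leaf.positions)

    _recurse(tree, {frozenset(): 1.0}, credit)
    return phi, float(f[frozenset()]), float(f[full])


def exact_shapley(value_fn, n_positions: int) -> np.ndarray:
    """Exhaustive Shapley values by 2^n enumeration (oracle; n small)."""
    all_sets = [frozenset(s) for r in range(n_positions + 1)
                for s in combinations(range(n_positions), r)]
    f = dict(zip(all_sets, np.asarray(value_fn(all_sets), dtype=float)))
    phi = np.zeros(n_positions)
    for i in range(n_positions):
        others = [j for j in range(n_positions) if j != i]
        for r in range(n_positions):
            w = _shapley_weight(r, n_positions)
            for S in combinations(others, r):
                S = frozenset(S)
                phi[i] += w * (f[S | {i}] - f[S])
    return phi


@dataclass
class AttributionVector:
    """Per-residue Shapley attributions for one kinase-peptide pair."""
    pair_id: str
    base_value: float
    peptide_part: np.ndarray       # (15,)
    kinase_part: np.ndarray        # (L,)
    prediction: float
    peptide: str = ""
    kinase_id: str = ""

    def __post_init__(self) -> None:
        self.peptide_part = np.asarray(self.peptide_part, dtype=float)
        self.kinase_part = np.asarray(self.kinase_part, dtype=float)
        gap = abs(self.base_value + self.peptide_part.sum()
                  + self.kinase_part.sum() - self.prediction)
        if gap > EFFICIENCY_TOL:
            raise AssertionError(
                f"efficiency violated for {self.pair_id}: residual {gap:.2e}")


class PartitionExplainer:
    """Owen-value attributions for the pair classifier.

    The value function masks every position outside the coalition by
    replacing its token with ``<mask>`` and reads the positive-class
    probability (or logit, with ``output="logit"``).
    """

    def __init__(self, model: MultitaskModel, output: str = "probability",
                 batch_size: int = 128):
        if output not in ("probability", "logit"):
            raise ValueError("output must be 'probability' or 'logit'")
        self.model = model
        self.output = output
        self.batch_size = batch_size

    def _values(self, base_ids: np.ndarray, on_sets: list[frozenset],
                n_positions: int) -> dict[frozenset, float]:
        """Batch-evaluate the model for each coalition of unmasked
        positions."""
        tok_index = np.array(
            [1 + i if i < PEPTIDE_LEN else 2 + i
             for i in range(n_positions)])     # position -> token index
        variants = np.tile(base_ids, (len(on_sets), 1))
        mask_id = self.model.vocab.mask_id
        for row, on in enumerate(on_sets):
            off = [i for i in range(n_positions) if i not in on]
            variants[row, tok_index[off]] = mask_id
        vals = np.empty(len(on_sets))
        for lo in range(0, len(on_sets), self.batch_size):
            chunk = variants[lo:lo + self.batch_size]
            if self.output == "probability":
                vals[lo:lo + len(chunk)] = self.model.predict_proba(chunk)
            else:
                h = self.model.encode(chunk, training=False)
                logits = self.model.classify_logits(h, chunk).data
                vals[lo:lo + len(chunk)] = logits[:, 1] - logits[:, 0]
        return dict(zip(on_sets, vals))

    def explain(self, peptide: str, kinase_domain: str,
                tree: PartitionNode | None = None,
                kinase_block: int = 8, pair_id: str = "",
                kinase_id: str = "") -> AttributionVector:
        tp = tokenize_pair(peptide, kinase_domain, self.model.vocab,
                           require_st_center=False)
        n_positions = PEPTIDE_LEN + len(kinase_domain)
        if tree is None:
            tree = build_pair_tree(len(kinase_domain), kinase_block)
        def value_fn(on_sets: list[frozenset]) -> np.ndarray:
            f = self._values(tp.token_ids, on_sets, n_positions)
            return np.array([f[s] for s in on_sets])

        phi, base, pred = owen_attributions(value_fn, n_positions, tree)
        return AttributionVector(
            pair_id=pair_id or f"{kinase_id}:{peptide}",
            base_value=base,
            peptide_part=phi[:PEPTIDE_LEN],
            kinase_part=phi[PEPTIDE_LEN:],
            prediction=pred,
            peptide=peptide, kinase_id=kinase_id)


def shap_attributions(model: MultitaskModel, peptide: str,
                      kinase_domain: str, output: str = "probability",
                      tree: PartitionNode | None = None,
                      kinase_block: int = 8,
                      pair_id: str = "", kinase_id: str = ""
                      ) -> AttributionVector:
    """One-call convenience wrapper around :class:`PartitionExplainer`."""
    return PartitionExplainer(model, output=output).explain(
        peptide, kinase_domain, tree=tree, kinase_block=kinase_block,
        pair_id=pair_id, kinase_id=kinase_id)


def attribution_polarity_summary(attribution_set: list[AttributionVector]
                                 ) -> dict:
    """Mean and positive-sign rate of per-part contribution sums —
    the descriptive report behind 'peptide pushes positive, kinase pushes
    negative' style analyses."""
    if not attribution_set:
        raise ValueError("need at least one attribution vector")
    pep_sums = np.array([a.peptide_part.sum() for a in attribution_set])
    kin_parts = [a.kinase_part for a in attribution_set]
    out = {
        "n": len(attribution_set),
        "peptide_mean_sum": float(pep_sums.mean()),
        "peptide_positive_rate": float(np.mean(pep_sums > 0)),
    }
    if all(kp.size == 0 for kp in kin_parts):
        out["kinase_part"] = "absent"
    else:
        kin_sums = np.array([kp.sum() for kp in kin_parts])
        out["kinase_mean_sum"] = float(kin_sums.mean())
        out["kinase_positive_rate"] = float(np.mean(kin_sums > 0))
    return out


# ---------------------------------------------------------------------------
# motif decomposition
# ---------------------------------------------------------------------------

def sequence_logo_matrix(peptides: list[str]) -> np.ndarray:
    """Column-normalized 15x20 position-frequency matrix."""
    if not peptides:
        raise ValueError("no peptides given")
    counts = np.zeros((PEPTIDE_LEN, 20))
    for seq in peptides:
        if len(seq) != PEPTIDE_LEN:
            raise ValueError("peptides must be 15-mers")
        for i, aa in enumerate(seq):
            counts[i, AA_INDEX[aa]] += 1
    return counts / counts.sum(axis=1, keepdims=True)


def information_content(freqs: np.ndarray) -> np.ndarray:
    """Per-position information content: log2(20) minus column entropy."""
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(freqs > 0, freqs * np.log2(freqs), 0.0)
    return np.log2(20) + plogp.sum(axis=1)


@dataclass
class MotifCluster:
    kinase_id: str
    member_pair_ids: list[str]
    exemplar_id: str
    logo: np.ndarray                        # 15x20 frequency matrix
    mean_attribution: np.ndarray = field(default=None)  # type: ignore


def motif_decomposition(kinase_id: str,
                        attribution_set: list[AttributionVector],
                        damping: float = 0.9,
                        preference: float | None = None,
                        use_full_vector: bool = False,
                        random_state: int = 0) -> list[MotifCluster]:
    """Affinity propagation over attribution vectors of one kinase's true
    positives; similarity is negative squared Euclidean distance between
    peptide-part vectors (or full vectors with `use_full_vector`).
    Exemplars anchor the clusters; member peptides are tabulated into
    per-cluster sequence-logo matrices."""
    if not attribution_set:
        raise ValueError("no attributions given")
    bad = [a.pair_id for a in attribution_set if a.kinase_id
           and a.kinase_id != kinase_id]
    if bad:
        raise ValueError(f"attributions not from kinase {kinase_id}: {bad}")
    X = np.array([np.concatenate([a.peptide_part, a.kinase_part])
                  if use_full_vector else a.peptide_part
                  for a in attribution_set])
    if len(X) == 1:
        labels = np.array([0])
        exemplars = np.array([0])
    else:
        from sklearn.cluster import AffinityPropagation
        from sklearn.exceptions import ConvergenceWarning
        d2 = ((X[:, None, :] - X[None, :, :]) ** 2).sum(-1)
        S = -d2
        if preference is None:
            preference = float(np.median(S))
        ap = AffinityPropagation(affinity="precomputed", damping=damping,
                                 preference=preference,
                                 random_state=random_state, max_iter=500)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            labels = ap.fit_predict(S)
        if (labels < 0).any() or ap.cluster_centers_indices_ is None or \
                len(ap.cluster_centers_indices_) == 0:
            warnings.warn("affinity propagation did not converge; "
                          "returning a single cluster")
            labels = np.zeros(len(X), dtype=int)
            exemplars = np.array([0])
        else:
            exemplars = ap.cluster_centers_indices_
    clusters = []
    for c in sorted(set(labels.tolist())):
        members = [a for a, l in zip(attribution_set, labels) if l == c]
        seqs = [a.peptide for a in members]
        clusters.append(MotifCluster(
            kinase_id=kinase_id,
            member_pair_ids=[a.pair_id for a in members],
            exemplar_id=attribution_set[exemplars[c]].pair_id
            if c < len(exemplars) else members[0].pair_id,
            logo=sequence_logo_matrix(seqs),
            mean_attribution=np.mean([a.peptide_part for a in members],
                                     axis=0)))
    return clusters


def motif_recovery_rate(per_kinase_attributions:
                        dict[str, list[AttributionVector]],
                        determinant_offsets: dict[str, list[int]]) -> float:
    """Fraction of kinases whose top mean-|peptide attribution| flank
    position is one of their planted determinant offsets (flank offsets
    are -7..+7 around the central residue, which is excluded)."""
    hits = 0
    for kid, attrs in per_kinase_attributions.items():
        mean_abs = np.mean([np.abs(a.peptide_part) for a in attrs], axis=0)
        flank = [(abs_val, row) for row, abs_val in enumerate(mean_abs)
                 if row != CENTER_ROW]
        top_row = max(flank)[1]
        if (top_row - CENTER_ROW) in determinant_offsets[kid]:
            hits += 1
    return hits / len(per_kinase_attributions)


def plot_logo(freqs: np.ndarray, path: str, title: str = "") -> None:
    """Render a sequence logo (letters scaled by information content)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from .vocab import AMINO_ACIDS
    ic = information_content(freqs)
    fig, ax = plt.subplots(figsize=(8, 2.5))
    for pos in range(freqs.shape[0]):
        heights = freqs[pos] * ic[pos]
        order = np.argsort(heights)
        y = 0.0
        for a in order:
            h = heights[a]
            if h < 1e-3:
                continue
            ax.text(pos - 7, y + h / 2, AMINO_ACIDS[a], ha="center",
                    va="center", fontsize=6 + 10 * min(h / np.log2(20), 1),
                    family="monospace")
            y += h
    ax.set_xlim(-8, 8)
    ax.set_ylim(0, np.log2(20))
    ax.set_xlabel("flank position")
    ax.set_ylabel("bits")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
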