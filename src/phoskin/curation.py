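"""Dataset curation: percentile tiers, identity/Hamming clustering,
representative selection, easy-negative pairing, and splits.

The pipeline mirrors standard peptide-array curation practice: pairs with
percentile > 90 are positives, < 50 are hard negatives, the band between
is discarded; kinases are clustered at 70% identity (greedy, CD-HIT-like,
descending length order), peptides greedily by Hamming distance <= 5 over
the 11 central residues (serine and threonine sites clustered separately);
one representative pair survives per unique (tier, kinase cluster, peptide
cluster) combination; positives split 60:20:20 and validation/test carry
the three tiers at 1:1:1.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic import KinaseRecord, PeptideRecord

POSITIVE = "positive"
HARD_NEGATIVE = "hard_negative"
EASY_NEGATIVE = "easy_negative"
TIERS = (POSITIVE, HARD_NEGATIVE, EASY_NEGATIVE)


@dataclass
class CurationConfig:
    positive_threshold: float = 90.0        # strict >
    hard_negative_threshold: float = 50.0   # strict <
    kinase_identity_threshold: float = 0.70
    peptide_hamming_cutoff: int = 5
    peptide_window: int = 11
    split_ratios: tuple[float, float, float] = (0.6, 0.2, 0.2)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.hard_negative_threshold < self.positive_threshold \
                <= 100:
            raise ValueError("need 0 <= hard_negative_threshold < "
                             "positive_threshold <= 100")
        if self.peptide_window % 2 == 0 or self.peptide_window > 15:
            raise ValueError("peptide window must be odd and <= 15")
        if any(r <= 0 for r in self.split_ratios):
            raise ValueError("split ratios must be positive")


@dataclass
class PairExample:
    kinase_id: str
    peptide: PeptideRecord
    percentile: float | None
    tier: str
    kinase_cluster: str | None = None
    peptide_cluster: str | None = None
    split: str = "unassigned"

    @property
    def key(self) -> tuple[str, str]:
        return (self.kinase_id, self.peptide.sequence)

    @property
    def label(self) -> int:
        return 1 if self.tier == POSITIVE else 0


@dataclass
class ClusterAssignment:
    entity_id: str
    cluster_id: str
    is_representative: bool


def label_pairs(pairs: list[tuple[str, PeptideRecord, float]],
                config: CurationConfig | None = None
                ) -> tuple[list[PairExample], list[PairExample]]:
    """Assign tiers by strict thresholds; pairs falling in the middle band
    are returned separately as discards."""
    config = config or CurationConfig()
    labeled: list[PairExample] = []
    discarded: list[PairExample] = []
    for kid, pep, pct in pairs:
        if not 0.0 <= pct <= 100.0:
            raise ValueError(f"percentile {pct} outside [0, 100] "
                             f"for ({kid}, {pep.sequence})")
        if pct > config.positive_threshold:
            tier = POSITIVE
        elif pct < config.hard_negative_threshold:
            tier = HARD_NEGATIVE
        else:
            discarded.append(PairExample(kid, pep, pct, "discarded"))
            continue
        labeled.append(PairExample(kid, pep, pct, tier))
    return labeled, discarded


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

def sequence_identity(a: str, b: str) -> float:
    """Fraction of matching positions.

    Equal lengths: ungapped positional identity.  Unequal lengths: matches
    over alignment length from a global alignment with match 1, mismatch 0,
    gap -1 (the gaps only position the sequences).
    """
    if len(a) == len(b):
        if not a:
            raise ValueError("empty sequence")
        return sum(x == y for x, y in zip(a, b)) / len(a)
    from Bio import Align
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = 0
    aligner.open_gap_score = -1
    aligner.extend_gap_score = -1
    aln = aligner.align(a, b)[0]
    matches = sum(
        sum(a[i] == b[j] for i, j in zip(range(sa, ea), range(sb, eb)))
        for (sa, ea), (sb, eb) in zip(*aln.aligned))
    return matches / aln.length


def cluster_kinases(records: list[KinaseRecord],
                    identity_threshold: float = 0.70
                    ) -> list[ClusterAssignment]:
    """Greedy incremental clustering in descending length order (ties by
    kinase id): join the first cluster whose representative shares
    >= threshold identity, else found a new cluster."""
    if not records:
        raise ValueError("no kinase records to cluster")
    if not 0 < identity_threshold <= 1:
        raise ValueError("identity threshold must be in (0, 1]")
    order = sorted(records,
                   key=lambda r: (-len(r.domain_sequence), r.kinase_id))
    reps: list[tuple[str, str]] = []     # (cluster_id, rep sequence)
    out: list[ClusterAssignment] = []
    for rec in order:
        for cid, rep_seq in reps:
            if sequence_identity(rec.domain_sequence, rep_seq) \
                    >= identity_threshold:
                out.append(ClusterAssignment(rec.kinase_id, cid, False))
                break
        else:
            cid = f"KC{len(reps):03d}"
            reps.append((cid, rec.domain_sequence))
            out.append(ClusterAssignment(rec.kinase_id, cid, True))
    return out


def _window_bounds(window: int, length: int = 15) -> tuple[int, int]:
    if window > length:
        raise ValueError(f"window {window} exceeds peptide length {length}")
    start = (length - window) // 2
    return start, start + window


def hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def cluster_peptides_greedy(peptides: list[PeptideRecord], cutoff: int = 5,
                            window: int = 11, cluster_prefix: str = "PC",
                            order: np.ndarray | None = None
                            ) -> list[ClusterAssignment]:
    """One greedy pass in input order (or the given permutation): join the
    first cluster whose representative is within Hamming distance
    <= cutoff over the `window` central residues, else found a cluster.

    Callers should pre-partition peptides by central residue (S vs T) and
    use distinct cluster prefixes; `cluster_peptides_by_center` does this.
    """
    lo, hi = _window_bounds(window)
    idx = np.arange(len(peptides)) if order is None else np.asarray(order)
    reps: list[tuple[str, str]] = []
    assigned: dict[int, ClusterAssignment] = {}
    for i in idx:
        core = peptides[i].sequence[lo:hi]
        for cid, rep_core in reps:
            if hamming(core, rep_core) <= cutoff:
                assigned[i] = ClusterAssignment(peptides[i].sequence, cid,
                                                False)
                break
        else:
            cid = f"{cluster_prefix}{len(reps):05d}"
            reps.append((cid, core))
            assigned[i] = ClusterAssignment(peptides[i].sequence, cid, True)
    return [assigned[i] for i in range(len(peptides))]


def cluster_peptides_by_center(peptides: list[PeptideRecord],
                               cutoff: int = 5, window: int = 11,
                               shuffle_seed: int | None = None,
                               pool_tag: str = "") -> dict[str, str]:
    """Cluster serine and threonine sites separately; returns
    peptide sequence -> cluster id (prefixes "S"/"T" keep them disjoint,
    `pool_tag` keeps separate pools' ids disjoint).
    """
    mapping: dict[str, str] = {}
    for center in "ST":
        subset = [p for p in peptides if p.central == center]
        if not subset:
            continue
        order = None
        if shuffle_seed is not None:
            order = np.random.default_rng(shuffle_seed).permutation(
                len(subset))
        for a in cluster_peptides_greedy(subset, cutoff, window,
                                         cluster_prefix=
                                         f"{pool_tag}{center}C",
                                         order=order):
            mapping[a.entity_id] = a.cluster_id
    return mapping


def attach_clusters(pairs: list[PairExample],
                    kinase_clusters: dict[str, str],
                    peptide_clusters: dict[str, str]) -> list[PairExample]:
    for ex in pairs:
        ex.kinase_cluster = kinase_clusters[ex.kinase_id]
        ex.peptide_cluster = peptide_clusters[ex.peptide.sequence]
    return pairs


def select_representatives(pairs: list[PairExample],
                           seed: int = 0) -> list[PairExample]:
    """Keep one uniformly random pair per (tier, kinase cluster, peptide
    cluster) combination; applied per tier independently."""
    rng = np.random.default_rng(seed)
    groups: dict[tuple[str, str, str], list[PairExample]] = {}
    for ex in pairs:
        if ex.kinase_cluster is None or ex.peptide_cluster is None:
            raise ValueError(f"pair {ex.key} is missing a cluster id")
        groups.setdefault((ex.tier, ex.kinase_cluster, ex.peptide_cluster),
                          []).append(ex)
    kept: list[PairExample] = []
    for key in sorted(groups):
        members = groups[key]
        kept.append(members[rng.integers(len(members))])
    order = {id(ex): i for i, ex in enumerate(pairs)}
    kept.sort(key=lambda ex: order[id(ex)])
    return kept


def generate_easy_negatives(kinases: list[KinaseRecord],
                            nonphospho_peptides: list[PeptideRecord],
                            n: int, seed: int = 0,
                            kinase_clusters: dict[str, str] | None = None,
                            peptide_clusters: dict[str, str] | None = None,
                            config: CurationConfig | None = None
                            ) -> list[PairExample]:
    """Randomly pair kinases with never-phosphorylated peptides (sampling
    without replacement over the cross-product), then deduplicate with the
    same unique-cluster-combination filter as the scored tiers."""
    if not kinases or not nonphospho_peptides:
        raise ValueError("both pools must be non-empty")
    config = config or CurationConfig()
    total = len(kinases) * len(nonphospho_peptides)
    if n > total:
        raise ValueError(f"requested {n} pairings but only {total} unique "
                         "combinations are attainable")
    rng = np.random.default_rng(seed)
    flat = rng.choice(total, size=n, replace=False)
    if kinase_clusters is None:
        kinase_clusters = {a.entity_id: a.cluster_id for a in
                           cluster_kinases(kinases,
                                           config.kinase_identity_threshold)}
    if peptide_clusters is None:
        peptide_clusters = cluster_peptides_by_center(
            nonphospho_peptides, config.peptide_hamming_cutoff,
            config.peptide_window)
    pairs = []
    for f in flat:
        kin = kinases[f // len(nonphospho_peptides)]
        pep = nonphospho_peptides[f % len(nonphospho_peptides)]
        pairs.append(PairExample(kin.kinase_id, pep, None, EASY_NEGATIVE,
                                 kinase_clusters[kin.kinase_id],
                                 peptide_clusters[pep.sequence]))
    return select_representatives(pairs, seed=seed + 1)


def collect_easy_negatives(kinases: list[KinaseRecord],
                           nonphospho_peptides: list[PeptideRecord],
                           n_target: int, seed: int = 0,
                           kinase_clusters: dict[str, str] | None = None,
                           peptide_clusters: dict[str, str] | None = None,
                           config: CurationConfig | None = None
                           ) -> list[PairExample]:
    """Walk a seeded permutation of the cross-product, keeping the first
    pair of each unseen cluster combination, until `n_target` survive."""
    if not kinases or not nonphospho_peptides:
        raise ValueError("both pools must be non-empty")
    config = config or CurationConfig()
    if kinase_clusters is None:
        kinase_clusters = {a.entity_id: a.cluster_id for a in
                           cluster_kinases(kinases,
                                           config.kinase_identity_threshold)}
    if peptide_clusters is None:
        peptide_clusters = cluster_peptides_by_center(
            nonphospho_peptides, config.peptide_hamming_cutoff,
            config.peptide_window)
    rng = np.random.default_rng(seed)
    total = len(kinases) * len(nonphospho_peptides)
    seen: set[tuple[str, str]] = set()
    out: list[PairExample] = []
    for f in rng.permutation(total):
        kin = kinases[f // len(nonphospho_peptides)]
        pep = nonphospho_peptides[f % len(nonphospho_peptides)]
        combo = (kinase_clusters[kin.kinase_id],
                 peptide_clusters[pep.sequence])
        if combo in seen:
            continue
        seen.add(combo)
        out.append(PairExample(kin.kinase_id, pep, None, EASY_NEGATIVE,
                               combo[0], combo[1]))
        if len(out) == n_target:
            return out
    raise ValueError(f"only {len(out)} unique cluster combinations "
                     f"attainable, {n_target} requested")


# ---------------------------------------------------------------------------
# splits
# ---------------------------------------------------------------------------

def make_splits(positives: list[PairExample],
                hard_negatives: list[PairExample],
                easy_negatives: list[PairExample],
                config: CurationConfig | None = None) -> list[PairExample]:
    """Partition positives 60:20:20 (floor, remainder to train); val and
    test receive hard and easy negatives matching their positive counts
    (1:1:1); remaining negatives go to train."""
    config = config or CurationConfig()
    keys: set[tuple[str, str]] = set()
    for pool in (positives, hard_negatives, easy_negatives):
        for ex in pool:
            if ex.key in keys:
                raise ValueError(f"pair {ex.key} appears in multiple pools")
            keys.add(ex.key)
    rng = np.random.default_rng(config.seed)
    r_train, r_val, r_test = (np.asarray(config.split_ratios)
                              / sum(config.split_ratios))
    n = len(positives)
    n_val, n_test = int(np.floor(n * r_val)), int(np.floor(n * r_test))
    perm = rng.permutation(n)
    val_idx = set(perm[:n_val].tolist())
    test_idx = set(perm[n_val:n_val + n_test].tolist())
    for i, ex in enumerate(positives):
        ex.split = "val" if i in val_idx else \
                   "test" if i in test_idx else "train"
    for pool, name in ((hard_negatives, "hard"), (easy_negatives, "easy")):
        need = n_val + n_test
        if len(pool) < need:
            raise ValueError(
                f"{name}-negative pool too small: {len(pool)} available, "
                f"{need} needed for 1:1:1 validation/test "
                f"(shortfall {need - len(pool)})")
        perm = rng.permutation(len(pool))
        for j, i in enumerate(perm):
            pool[i].split = ("val" if j < n_val else
                             "test" if j < n_val + n_test else "train")
    return positives + hard_negatives + easy_negatives


def split_of(examples: list[PairExample], split: str) -> list[PairExample]:
    return [ex for ex in examples if ex.split == split]


def check_tier_invariants(examples: list[PairExample],
                          config: CurationConfig | None = None) -> None:
    """Assertable scan over the tier definitions."""
    config = config or CurationConfig()
    for ex in examples:
        if ex.tier == POSITIVE:
            ok = ex.percentile is not None and \
                ex.percentile > config.positive_threshold
        elif ex.tier == HARD_NEGATIVE:
            ok = ex.percentile is not None and \
                ex.percentile < config.hard_negative_threshold
        elif ex.tier == EASY_NEGATIVE:
            ok = ex.percentile is None and not ex.peptide.phospho_evidence
        else:
            ok = False
        if not ok:
            raise AssertionError(f"tier invariant violated for {ex.key}: "
                                 f"tier={ex.tier}, pct={ex.percentile}")


# ---------------------------------------------------------------------------
# manifest IO
# ---------------------------------------------------------------------------

def dataset_to_frame(examples: list[PairExample]) -> pd.DataFrame:
    return pd.DataFrame({
        "kinase_id": [e.kinase_id for e in examples],
        "peptide": [e.peptide.sequence for e in examples],
        "percentile": [e.percentile for e in examples],
        "tier": [e.tier for e in examples],
        "kinase_cluster": [e.kinase_cluster for e in examples],
        "peptide_cluster": [e.peptide_cluster for e in examples],
        "split": [e.split for e in examples],
    })


def write_dataset_manifest(examples: list[PairExample], path: str | Path,
                           config: CurationConfig | None = None,
                           provenance_path: str | Path | None = None) -> None:
    dataset_to_frame(examples).to_csv(path, sep="\t", index=False)
    if provenance_path is not None:
        prov = {"config": asdict(config or CurationConfig()),
                "ordering": "kinases: descending length then id; "
                            "peptides: input order"}
        Path(provenance_path).write_text(json.dumps(prov, indent=2))
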