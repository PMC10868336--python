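"""Synthetic kinase universes with planted substrate-specificity motifs.

Every downstream stage (curation, training, evaluation, attribution) is
exercised against worlds generated here, where the ground truth is known:
kinase families are mutational clusters around an ancestor domain
sequence, each family carries a position-specific scoring profile over the
15-mer flanking window (-7..+7 around the phospho-acceptor), and peptide
percentile scores are rank percentiles of additive log-odds scores within
a reference pool — the standard peptide-array readout.

Nothing here tries to emulate real kinome sequence statistics or array
chemistry; the point is a controllable world with recoverable motifs.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .vocab import AMINO_ACIDS

AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}
#: flank offsets scored by a profile (the central 0 position is excluded)
FLANK_OFFSETS = tuple(o for o in range(-7, 8) if o != 0)
CENTER_ROW = 7  # row of position 0 in the 15x20 weight matrix


def flank_to_row(offset: int) -> int:
    """Map a flank offset in -7..+7 (non-zero) to a weight-matrix row."""
    if not -7 <= offset <= 7 or offset == 0:
        raise ValueError(f"flank offset must be in -7..+7 and non-zero, "
                         f"got {offset}")
    return offset + 7


@dataclass
class MotifDeterminant:
    """One planted specificity determinant: residue set at a flank offset."""
    offset: int          # -7..+7, non-zero
    residues: str        # e.g. "R" or "DE"
    weight: float        # log-odds added for a matching residue

    def __post_init__(self) -> None:
        flank_to_row(self.offset)
        bad = [r for r in self.residues if r not in AA_INDEX]
        if bad:
            raise ValueError(
                f"invalid residue(s) {bad} in motif determinant "
                f"(offset={self.offset}, residues={self.residues!r})")


@dataclass
class SpecificityProfile:
    """Additive log-odds scoring matrix over the 15-mer window."""
    kinase_id: str
    weights: np.ndarray            # (15, 20); row CENTER_ROW is ignored
    central_pref: np.ndarray       # (2,) log-weights for (S, T)
    determinants: list[MotifDeterminant] = field(default_factory=list)
    #: if set, each sampled substrate commits to ONE determinant (a kinase
    #: with several distinct specificity modes rather than one additive
    #: motif); scoring stays additive over the full matrix
    mode_split: bool = False

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.central_pref = np.asarray(self.central_pref, dtype=float)
        if self.weights.shape != (15, 20):
            raise ValueError("profile weights must be 15x20")
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("profile weights must be finite")

    def raw_score(self, peptide_seq: str) -> float:
        if len(peptide_seq) != 15:
            raise ValueError("peptide must be length 15")
        s = 0.0
        for row, aa in enumerate(peptide_seq):
            if row == CENTER_ROW:
                continue
            s += self.weights[row, AA_INDEX[aa]]
        s += self.central_pref[0 if peptide_seq[CENTER_ROW] == "S" else 1]
        return s

    def raw_scores(self, seq_matrix: np.ndarray) -> np.ndarray:
        """Vectorized scoring of an (n, 15) residue-index matrix."""
        rows = np.arange(15)
        per_pos = self.weights[rows[None, :], seq_matrix]  # (n, 15)
        per_pos[:, CENTER_ROW] = 0.0
        central = np.where(seq_matrix[:, CENTER_ROW] == AA_INDEX["S"],
                           self.central_pref[0], self.central_pref[1])
        return per_pos.sum(axis=1) + central


@dataclass
class KinaseRecord:
    kinase_id: str
    domain_sequence: str
    family: str
    group: str
    specificity_group: str
    profile: SpecificityProfile | None = None


@dataclass
class PeptideRecord:
    sequence: str
    phospho_evidence: bool
    source_id: str = ""
    source_pos: int = 0

    def __post_init__(self) -> None:
        if len(self.sequence) != 15:
            raise ValueError(f"peptide must be length 15, "
                             f"got {len(self.sequence)}")
        if self.central not in "ST":
            raise ValueError(f"central residue must be S or T, "
                             f"got {self.central!r}")

    @property
    def central(self) -> str:
        return self.sequence[CENTER_ROW]


# Canonical-style motif classes cycled over families: one dominant
# determinant each (what the attribution analysis should recover) plus a
# weaker secondary one.
_MOTIF_LIBRARY: list[tuple[str, list[tuple[int, str, float]]]] = [
    ("basophilic", [(-3, "R", 3.5), (-2, "K", 1.0)]),
    ("acidophilic", [(-2, "DE", 3.5), (-4, "E", 1.0)]),
    ("proline_directed", [(1, "P", 3.5), (-6, "P", 1.0)]),
    ("hydrophobic_plus3", [(3, "F", 3.5), (1, "L", 1.0)]),
    ("basophilic_k", [(-5, "K", 3.5), (2, "R", 1.0)]),
    ("acidic_down", [(4, "DE", 3.5), (6, "D", 1.0)]),
    ("glycine_directed", [(-1, "G", 3.5), (5, "G", 1.0)]),
    ("aromatic", [(2, "Y", 3.5), (-6, "W", 1.0)]),
]

_GROUP_NAMES = ("AGC", "CAMK", "CMGC", "CK1", "STE", "TKL", "other",
                "atypical")


def default_motif_specs(n_families: int) -> list[list[MotifDeterminant]]:
    """One motif spec per family, cycling the library."""
    specs = []
    for f in range(n_families):
        name, dets = _MOTIF_LIBRARY[f % len(_MOTIF_LIBRARY)]
        specs.append([MotifDeterminant(*d) for d in dets])
    return specs


def bimodal_motif_spec() -> list[MotifDeterminant]:
    """Two disjoint strong determinants — a kinase with two specificity
    modes, for motif-decomposition tests."""
    return [MotifDeterminant(-3, "R", 3.5), MotifDeterminant(2, "DE", 3.5)]


def _spec_name(determinants: list[MotifDeterminant], family_index: int) -> str:
    for f, (name, dets) in enumerate(_MOTIF_LIBRARY):
        lib = [MotifDeterminant(*d) for d in dets]
        if ([(d.offset, d.residues) for d in lib]
                == [(d.offset, d.residues) for d in determinants]):
            return name
    return f"custom{family_index}"


def _random_sequence(length: int, freqs: np.ndarray,
                     rng: np.random.Generator) -> str:
    idx = rng.choice(20, size=length, p=freqs)
    return "".join(AMINO_ACIDS[i] for i in idx)


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    out = list(seq)
    hits = np.flatnonzero(rng.random(len(seq)) < rate)
    for i in hits:
        choices = [a for a in AMINO_ACIDS if a != out[i]]
        out[i] = choices[rng.integers(len(choices))]
    return "".join(out)


def _profile_from_spec(kinase_id: str, determinants: list[MotifDeterminant],
                       central_pref: np.ndarray, jitter_sd: float,
                       rng: np.random.Generator) -> SpecificityProfile:
    w = np.zeros((15, 20))
    for det in determinants:
        for r in det.residues:
            w[flank_to_row(det.offset), AA_INDEX[r]] += det.weight
    if jitter_sd > 0:
        w = w + rng.normal(0.0, jitter_sd, w.shape)
        w[CENTER_ROW, :] = 0.0
    margin = min(d.weight for d in determinants)
    for det in determinants:
        row = flank_to_row(det.offset)
        cell = max(w[row, AA_INDEX[r]] for r in det.residues)
        background = np.median(w[row])
        if cell - background < margin / 2:
            # jitter should never drown a determinant; regenerate the cell
            for r in det.residues:
                w[row, AA_INDEX[r]] = det.weight
    return SpecificityProfile(kinase_id=kinase_id, weights=w,
                              central_pref=central_pref.copy(),
                              determinants=list(determinants))


def generate_kinase_universe(n_families: int, kinases_per_family: int,
                             domain_length: int = 250,
                             within_family_mutation_rate: float = 0.05,
                             motif_spec: list[list[MotifDeterminant]]
                             | None = None,
                             seed: int = 0,
                             profile_jitter_sd: float = 0.1,
                             background_freqs: np.ndarray | None = None,
                             mode_split_families: frozenset[int] | set[int]
                             = frozenset()) -> list[KinaseRecord]:
    """Families = mutational clusters of independent ancestor sequences,
    sharing a family profile up to small per-kinase jitter."""
    if n_families < 1:
        raise ValueError("n_families must be >= 1")
    if not 0 <= within_family_mutation_rate < 0.5:
        raise ValueError("mutation rate must be in [0, 0.5)")
    if motif_spec is None:
        motif_spec = default_motif_specs(n_families)
    if len(motif_spec) != n_families:
        raise ValueError("motif_spec must name one motif list per family")
    freqs = (np.full(20, 0.05) if background_freqs is None
             else np.asarray(background_freqs, dtype=float))
    rng = np.random.default_rng(seed)
    records: list[KinaseRecord] = []
    for f in range(n_families):
        family = f"FAM{f:02d}"
        group = _GROUP_NAMES[f % len(_GROUP_NAMES)]
        ancestor = _random_sequence(domain_length, freqs, rng)
        # family-level S/T preference alternates with a mild margin
        central = np.array([0.7, 0.0]) if f % 2 == 0 else np.array([0.0, 0.7])
        spec_group = _spec_name(motif_spec[f], f)
        for k in range(kinases_per_family):
            kid = f"{family}_K{k:02d}"
            dom = _mutate(ancestor, within_family_mutation_rate, rng)
            prof = _profile_from_spec(kid, motif_spec[f], central,
                                      profile_jitter_sd, rng)
            if f in mode_split_families:
                prof.mode_split = True
            records.append(KinaseRecord(kinase_id=kid, domain_sequence=dom,
                                        family=family, group=group,
                                        specificity_group=spec_group,
                                        profile=prof))
    return records


def peptides_to_matrix(peptides: list[PeptideRecord]) -> np.ndarray:
    """(n, 15) residue-index matrix for vectorized scoring."""
    return np.array([[AA_INDEX[a] for a in p.sequence] for p in peptides],
                    dtype=np.int64)


def _sample_profile_peptide(profile: SpecificityProfile, freqs: np.ndarray,
                            rng: np.random.Generator) -> str:
    """Draw a 15-mer position-wise from background tilted by the profile.

    For a mode-split profile only one (randomly chosen) determinant's
    position is tilted, so the substrate pool is a mixture of motif modes.
    """
    tilt_rows: set[int] | None = None
    if profile.mode_split and profile.determinants:
        det = profile.determinants[rng.integers(len(profile.determinants))]
        tilt_rows = {flank_to_row(det.offset)}
    out = []
    for row in range(15):
        if row == CENTER_ROW:
            p = np.exp(profile.central_pref)
            out.append("ST"[rng.choice(2, p=p / p.sum())])
            continue
        if tilt_rows is not None and row not in tilt_rows:
            p = freqs
        else:
            p = freqs * np.exp(profile.weights[row])
        out.append(AMINO_ACIDS[rng.choice(20, p=p / p.sum())])
    return "".join(out)


def _sample_background_peptide(freqs: np.ndarray,
                               rng: np.random.Generator) -> str:
    idx = rng.choice(20, size=15, p=freqs)
    seq = list(AMINO_ACIDS[i] for i in idx)
    seq[CENTER_ROW] = "ST"[rng.integers(2)]
    return "".join(seq)


def generate_peptide_pools(n_phospho: int, n_nonphospho: int,
                           profiles: list[SpecificityProfile],
                           background_freqs: np.ndarray | None = None,
                           seed: int = 0,
                           rejection_ceiling: float = 80.0,
                           reference_size: int = 500,
                           max_attempt_factor: int = 50
                           ) -> tuple[list[PeptideRecord],
                                      list[PeptideRecord]]:
    """Phosphorylatable pool (profile-enriched) and easy-negative pool
    (background, rejected if any profile would rank it above the ceiling).
    """
    freqs = (np.full(20, 0.05) if background_freqs is None
             else np.asarray(background_freqs, dtype=float))
    if abs(freqs.sum() - 1.0) > 1e-9:
        raise ValueError("background_freqs must sum to 1")
    if n_phospho > 0 and not profiles:
        raise ValueError("profiles required to generate a phospho pool")
    rng = np.random.default_rng(seed)

    phospho: list[PeptideRecord] = []
    for i in range(n_phospho):
        prof = profiles[rng.integers(len(profiles))]
        phospho.append(PeptideRecord(
            sequence=_sample_profile_peptide(prof, freqs, rng),
            phospho_evidence=True, source_id=prof.kinase_id, source_pos=i))

    nonphospho: list[PeptideRecord] = []
    if n_nonphospho > 0:
        thresholds = None
        if profiles:
            # ceiling is a percentile within the phosphorylatable
            # (profile-enriched) population — the same ranking population
            # percentile scores use — so only accidental motif matches
            # are rejected, not ordinary background fluctuation
            if phospho:
                ref_mat = peptides_to_matrix(phospho)
            else:
                ref = [_sample_profile_peptide(
                    profiles[rng.integers(len(profiles))], freqs, rng)
                    for _ in range(reference_size)]
                ref_mat = np.array([[AA_INDEX[a] for a in s] for s in ref])
            thresholds = np.array(
                [np.percentile(p.raw_scores(ref_mat), rejection_ceiling)
                 for p in profiles])
        attempts = 0
        cap = max_attempt_factor * n_nonphospho
        while len(nonphospho) < n_nonphospho:
            if attempts >= cap:
                raise RuntimeError(
                    f"easy-negative rejection ceiling {rejection_ceiling} "
                    f"infeasible: {len(nonphospho)}/{n_nonphospho} accepted "
                    f"after {attempts} attempts")
            attempts += 1
            seq = _sample_background_peptide(freqs, rng)
            if thresholds is not None:
                mat = np.array([[AA_INDEX[a] for a in seq]])
                scores = np.array([p.raw_scores(mat)[0] for p in profiles])
                if np.any(scores > thresholds):
                    continue
            nonphospho.append(PeptideRecord(
                sequence=seq, phospho_evidence=False,
                source_id="background", source_pos=len(nonphospho)))
    return phospho, nonphospho


def score_percentile(profile: SpecificityProfile, peptide: PeptideRecord,
                     reference_pool: list[PeptideRecord]) -> float:
    """Rank percentile (mean rank for ties) of the peptide's raw score
    within the reference pool, treated as the ranking population."""
    if not reference_pool:
        raise ValueError("reference pool must be non-empty")
    s = profile.raw_score(peptide.sequence)
    pool_scores = profile.raw_scores(peptides_to_matrix(reference_pool))
    n = len(pool_scores)
    less = int(np.sum(pool_scores < s - 1e-12))
    equal = int(np.sum(np.abs(pool_scores - s) <= 1e-12))
    if equal == 0:   # peptide outside the pool: insert it conceptually
        pool_scores = np.append(pool_scores, s)
        n += 1
        equal = 1
    mean_rank = less + (equal + 1) / 2.0
    return 100.0 * mean_rank / n


def percentile_matrix(profiles: list[SpecificityProfile],
                      peptides: list[PeptideRecord]) -> np.ndarray:
    """(n_peptides, n_profiles) rank percentiles, each column ranked
    within the given peptide pool (mean rank for ties)."""
    mat = peptides_to_matrix(peptides)
    n = len(peptides)
    out = np.empty((n, len(profiles)))
    for j, prof in enumerate(profiles):
        scores = prof.raw_scores(mat)
        out[:, j] = 100.0 * rankdata(scores, method="average") / n
    return out


# ---------------------------------------------------------------------------
# bundled world + serialization
# ---------------------------------------------------------------------------

@dataclass
class SyntheticWorld:
    kinases: list[KinaseRecord]
    phospho_peptides: list[PeptideRecord]
    nonphospho_peptides: list[PeptideRecord]
    percentiles: np.ndarray             # (n_phospho_peptides, n_kinases)
    mlm_corpus: list[str]               # unlabeled kinase domains for MLM
    seed: int

    @property
    def kinase_ids(self) -> list[str]:
        return [k.kinase_id for k in self.kinases]

    def kinase_by_id(self, kid: str) -> KinaseRecord:
        return next(k for k in self.kinases if k.kinase_id == kid)

    def determinant_offsets(self, kinase_id: str) -> list[int]:
        prof = self.kinase_by_id(kinase_id).profile
        return [d.offset for d in prof.determinants]


def make_world(n_families: int = 8, kinases_per_family: int = 4,
               domain_length: int = 250, n_phospho: int = 1200,
               n_nonphospho: int = 600,
               within_family_mutation_rate: float = 0.05,
               motif_spec: list[list[MotifDeterminant]] | None = None,
               mlm_extra_per_family: int = 6, bimodal_family: int | None
               = None, seed: int = 0) -> SyntheticWorld:
    """Generate a complete world: kinases, pools, percentile matrix, and an
    unlabeled kinase corpus for masked-language-model pretraining.

    `bimodal_family` plants a two-mode specificity (R at -3 vs D/E at +2)
    in the named family, with mode-split substrate sampling.
    """
    if motif_spec is None:
        motif_spec = default_motif_specs(n_families)
    mode_split: set[int] = set()
    if bimodal_family is not None:
        motif_spec = list(motif_spec)
        motif_spec[bimodal_family] = bimodal_motif_spec()
        mode_split = {bimodal_family}
    kinases = generate_kinase_universe(
        n_families, kinases_per_family, domain_length,
        within_family_mutation_rate, motif_spec, seed=seed,
        mode_split_families=mode_split)
    profiles = [k.profile for k in kinases]
    phospho, nonphospho = generate_peptide_pools(
        n_phospho, n_nonphospho, profiles, seed=seed + 1)
    pct = percentile_matrix(profiles, phospho)
    # the MLM corpus emulates a broad kinase-domain collection: extra
    # (unlabeled) members of each family, never used in classification
    corpus_kin = generate_kinase_universe(
        n_families, mlm_extra_per_family, domain_length,
        within_family_mutation_rate,
        motif_spec or default_motif_specs(n_families), seed=seed + 2)
    corpus = [k.domain_sequence for k in corpus_kin]
    return SyntheticWorld(kinases=kinases, phospho_peptides=phospho,
                          nonphospho_peptides=nonphospho, percentiles=pct,
                          mlm_corpus=corpus, seed=seed)


def write_kinases_fasta(kinases: list[KinaseRecord], path: str | Path) -> None:
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord
    recs = [SeqRecord(Seq(k.domain_sequence),
                      id=f"{k.kinase_id}|{k.family}|{k.group}",
                      description="") for k in kinases]
    seqio_write(recs, str(path), "fasta")


def read_kinases_fasta(path: str | Path) -> list[KinaseRecord]:
    from Bio.SeqIO import parse
    out = []
    for rec in parse(str(path), "fasta"):
        kid, family, group = rec.id.split("|")
        out.append(KinaseRecord(kinase_id=kid, domain_sequence=str(rec.seq),
                                family=family, group=group,
                                specificity_group=""))
    return out


def write_percentile_tsv(peptides: list[PeptideRecord],
                         kinase_ids: list[str], percentiles: np.ndarray,
                         path: str | Path) -> None:
    df = pd.DataFrame(percentiles, columns=kinase_ids)
    df.insert(0, "peptide", [p.sequence for p in peptides])
    df.insert(1, "phospho_evidence", [p.phospho_evidence for p in peptides])
    df.to_csv(path, sep="\t", index=False)


def write_motif_manifest(world: SyntheticWorld, path: str | Path) -> None:
    manifest = {
        "seed": world.seed,
        "kinases": {
            k.kinase_id: {
                "family": k.family, "group": k.group,
                "specificity_group": k.specificity_group,
                "determinants": [
                    {"offset": d.offset, "residues": d.residues,
                     "weight": d.weight}
                    for d in (k.profile.determinants if k.profile else [])],
            } for k in world.kinases
        },
    }
    Path(path).write_text(json.dumps(manifest, indent=2))
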