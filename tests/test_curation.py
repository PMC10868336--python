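"""Curation pipeline: tier thresholds, greedy clustering vs brute-force
oracles, representative selection, easy negatives, splits."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from phoskin.curation import (EASY_NEGATIVE, HARD_NEGATIVE, POSITIVE,
                              ClusterAssignment, CurationConfig, PairExample,
                              attach_clusters, check_tier_invariants,
                              cluster_kinases, cluster_peptides_by_center,
                              cluster_peptides_greedy, collect_easy_negatives,
                              generate_easy_negatives, hamming, label_pairs,
                              make_splits, select_representatives,
                              sequence_identity, split_of)
from phoskin.synthetic import (AMINO_ACIDS, KinaseRecord, PeptideRecord,
                               generate_kinase_universe)


def _pep(seq):
    return PeptideRecord(sequence=seq, phospho_evidence=True)


def _nonphospho(seq):
    return PeptideRecord(sequence=seq, phospho_evidence=False)


def _random_pep(rng, phospho=True):
    s = rng.choice(list(AMINO_ACIDS), size=15)
    s[7] = "ST"[rng.integers(2)]
    return PeptideRecord(sequence="".join(s), phospho_evidence=phospho)


class TestLabelPairs:
    @pytest.mark.parametrize("pct,expected", [
        (95.0, POSITIVE), (42.0, HARD_NEGATIVE),
        (90.000001, POSITIVE), (49.999999, HARD_NEGATIVE),
    ])
    def test_tier_assignment(self, pct, expected):
        labeled, _ = label_pairs([("K1", _pep("AAAAAAASAAAAAAA"), pct)])
        assert labeled[0].tier == expected

    @pytest.mark.parametrize("pct", [70.0, 90.0, 50.0])
    def test_middle_band_and_boundaries_are_discarded(self, pct):
        """Strict inequalities: exactly 90 and exactly 50 match no rule."""
        labeled, discarded = label_pairs(
            [("K1", _pep("AAAAAAASAAAAAAA"), pct)])
        assert labeled == [] and len(discarded) == 1

    def test_out_of_range_percentile_rejected(self):
        with pytest.raises(ValueError):
            label_pairs([("K1", _pep("AAAAAAASAAAAAAA"), 101.0)])


class TestKinaseClustering:
    def test_identical_sequences_one_cluster(self):
        recs = [KinaseRecord(f"K{i}", "ACDEF" * 10, "F", "G", "")
                for i in range(2)]
        out = cluster_kinases(recs, 0.70)
        assert len({a.cluster_id for a in out}) == 1

    def test_disjoint_sequences_all_singletons(self):
        recs = [KinaseRecord("K0", "A" * 30, "F", "G", ""),
                KinaseRecord("K1", "C" * 30, "F", "G", ""),
                KinaseRecord("K2", "D" * 30, "F", "G", "")]
        out = cluster_kinases(recs, 0.70)
        assert len({a.cluster_id for a in out}) == 3
        assert all(a.is_representative for a in out)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            cluster_kinases([], 0.7)

    def test_each_cluster_has_exactly_one_representative(self):
        recs = generate_kinase_universe(4, 5, domain_length=60,
                                        within_family_mutation_rate=0.05,
                                        seed=2)
        out = cluster_kinases(recs, 0.70)
        by_cluster = {}
        for a in out:
            by_cluster.setdefault(a.cluster_id, []).append(a)
        for members in by_cluster.values():
            assert sum(m.is_representative for m in members) == 1

    def test_matches_bruteforce_greedy_oracle(self):
        """Replay the greedy rule with a full pairwise identity matrix and
        compare the resulting partitions."""
        recs = generate_kinase_universe(4, 5, domain_length=60,
                                        within_family_mutation_rate=0.05,
                                        seed=7)
        got = {a.entity_id: a.cluster_id for a in cluster_kinases(recs, 0.7)}
        # oracle: same ordering rule, identity from scratch
        order = sorted(recs, key=lambda r: (-len(r.domain_sequence),
                                            r.kinase_id))
        oracle: dict[str, int] = {}
        reps: list[tuple[int, str]] = []
        for rec in order:
            for cid, rep in reps:
                ident = sum(x == y for x, y in
                            zip(rec.domain_sequence, rep)) / len(rep)
                if ident >= 0.7:
                    oracle[rec.kinase_id] = cid
                    break
            else:
                oracle[rec.kinase_id] = len(reps)
                reps.append((len(reps), rec.domain_sequence))
        # same partition (up to cluster relabeling)
        for a in recs:
            for b in recs:
                assert (got[a.kinase_id] == got[b.kinase_id]) == \
                    (oracle[a.kinase_id] == oracle[b.kinase_id])

    def test_unequal_length_identity_uses_alignment(self):
        assert sequence_identity("ACDEFGH", "ACDEFGH") == 1.0
        ident = sequence_identity("ACDEFGHIKL", "ACDEFGH")
        assert 0.0 < ident < 1.0


class TestPeptideClustering:
    def test_outer_flanks_not_considered(self):
        """Two peptides identical on the 11 central residues but differing
        in all 4 outer flanks join the same cluster."""
        a = _pep("AACDEFGSHIKLMAA")
        b = _pep("WWCDEFGSHIKLMWW")
        out = cluster_peptides_greedy([a, b], cutoff=5, window=11)
        assert out[0].cluster_id == out[1].cluster_id

    def test_six_central_mismatches_split(self):
        a = _pep("AACDEFGSHIKLMAA")
        b = _pep("AAWWWWWSWIKLMAA")    # 6 mismatches in the 11-mer core
        core = a.sequence[2:13], b.sequence[2:13]
        assert hamming(*core) == 6
        out = cluster_peptides_greedy([a, b], cutoff=5, window=11)
        assert out[0].cluster_id != out[1].cluster_id

    def test_window_larger_than_peptide_rejected(self):
        with pytest.raises(ValueError):
            cluster_peptides_greedy([_pep("AAAAAAASAAAAAAA")], 5, 17)

    def test_matches_bruteforce_replay_on_random_instance(self, rng):
        peps = [_random_pep(rng) for _ in range(100)]
        got = cluster_peptides_greedy(peps, cutoff=5, window=11)
        reps: list[tuple[int, str]] = []
        for i, p in enumerate(peps):
            core = p.sequence[2:13]
            for ridx, rep in reps:
                if hamming(core, rep) <= 5:
                    expected = ridx
                    break
            else:
                expected = i
                reps.append((i, core))
            # compare partitions via the representative's index
            assert got[i].cluster_id == got[expected].cluster_id

    def test_center_partition_separates_s_and_t(self, rng):
        peps = [_random_pep(rng) for _ in range(60)]
        mapping = cluster_peptides_by_center(peps)
        for p in peps:
            assert mapping[p.sequence].startswith(p.central)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(0, 2 ** 31 - 1), st.integers(2, 60))
def test_greedy_peptide_clustering_agrees_with_oracle(seed, n):
    """Property: on random instances the one-pass greedy rule equals a
    brute-force replay over the full distance matrix."""
    rng = np.random.default_rng(seed)
    peps = []
    for _ in range(n):
        s = rng.choice(list("ACDES"), size=15)   # small alphabet: collisions
        s[7] = "S"
        peps.append(PeptideRecord(sequence="".join(s),
                                  phospho_evidence=True))
    got = cluster_peptides_greedy(peps, cutoff=5, window=11)
    reps = []
    for i, p in enumerate(peps):
        core = p.sequence[2:13]
        hit = None
        for ridx, rep in reps:
            if hamming(core, rep) <= 5:
                hit = ridx
                break
        if hit is None:
            reps.append((i, core))
            hit = i
        assert got[i].cluster_id == got[hit].cluster_id


def _mk_pairs(spec):
    """spec rows: (tier, kcluster, pcluster, seq)"""
    out = []
    for tier, kc, pc, seq in spec:
        pct = 95.0 if tier == POSITIVE else \
            40.0 if tier == HARD_NEGATIVE else None
        ev = tier != EASY_NEGATIVE
        out.append(PairExample("K" + kc, PeptideRecord(seq, ev), pct, tier,
                               kc, pc))
    return out


class TestRepresentativeSelection:
    def test_duplicate_combination_keeps_exactly_one(self):
        pairs = _mk_pairs([(POSITIVE, "K1", "P1", "AAAAAAASAAAAAAA"),
                           (POSITIVE, "K1", "P1", "CAAAAAASAAAAAAC")])
        assert len(select_representatives(pairs, seed=0)) == 1

    def test_same_peptide_cluster_different_kinase_clusters_both_kept(self):
        pairs = _mk_pairs([(POSITIVE, "K1", "P1", "AAAAAAASAAAAAAA"),
                           (POSITIVE, "K2", "P1", "AAAAAAASAAAAAAA")])
        assert len(select_representatives(pairs, seed=0)) == 2

    def test_distinct_combinations_identity(self):
        pairs = _mk_pairs([(POSITIVE, "K1", "P1", "AAAAAAASAAAAAAA"),
                           (POSITIVE, "K2", "P2", "CAAAAAASAAAAAAA"),
                           (HARD_NEGATIVE, "K1", "P1", "DAAAAAASAAAAAAA")])
        assert select_representatives(pairs, seed=0) == pairs

    def test_idempotent(self):
        rng = np.random.default_rng(3)
        pairs = _mk_pairs([
            (POSITIVE, f"K{rng.integers(3)}", f"P{rng.integers(4)}",
             "".join(rng.choice(list(AMINO_ACIDS), size=7)) + "S"
             + "".join(rng.choice(list(AMINO_ACIDS), size=7)))
            for _ in range(40)])
        once = select_representatives(pairs, seed=5)
        twice = select_representatives(once, seed=6)
        assert twice == once

    def test_missing_cluster_id_rejected(self):
        ex = PairExample("K1", _pep("AAAAAAASAAAAAAA"), 95.0, POSITIVE)
        with pytest.raises(ValueError):
            select_representatives([ex], seed=0)


class TestEasyNegatives:
    def _kinases(self):
        return [KinaseRecord("KA", "A" * 30, "F1", "G1", ""),
                KinaseRecord("KB", "C" * 30, "F2", "G2", "")]

    def _peps(self, rng, n=10):
        return [_random_pep(rng, phospho=False) for _ in range(n)]

    def test_basic_sampling(self, rng):
        pairs = generate_easy_negatives(self._kinases(), self._peps(rng),
                                        n=5, seed=1)
        assert all(p.tier == EASY_NEGATIVE and p.percentile is None
                   for p in pairs)
        assert len({p.key for p in pairs}) == len(pairs)

    def test_single_cluster_world_collapses_to_one_pair(self):
        kins = [KinaseRecord("KA", "A" * 30, "F", "G", ""),
                KinaseRecord("KB", "A" * 30, "F", "G", "")]
        peps = [_nonphospho("AAAAAAASAAAAAAA"),
                _nonphospho("AAAAAAASAAAAAAC")]
        pairs = generate_easy_negatives(kins, peps, n=4, seed=0)
        assert len(pairs) == 1

    def test_oversampling_rejected_with_attainable_count(self, rng):
        with pytest.raises(ValueError, match="20"):
            generate_easy_negatives(self._kinases(), self._peps(rng),
                                    n=21, seed=0)

    def test_collect_reaches_target_or_reports_shortfall(self, rng):
        kins = self._kinases()
        peps = self._peps(rng, 12)
        out = collect_easy_negatives(kins, peps, n_target=8, seed=2)
        assert len(out) == 8
        with pytest.raises(ValueError):
            collect_easy_negatives(kins, peps, n_target=10 ** 6, seed=2)


class TestSplits:
    def _pools(self, rng, n_pos=100, n_hard=100, n_easy=100):
        def mk(tier, n, ev):
            out = []
            for i in range(n):
                s = rng.choice(list(AMINO_ACIDS), size=15)
                s[7] = "S"
                pct = 95.0 if tier == POSITIVE else \
                    40.0 if tier == HARD_NEGATIVE else None
                out.append(PairExample(
                    f"K{tier[:1]}{i % 7}", PeptideRecord("".join(s), ev),
                    pct, tier, "KC0", f"PC{tier[:1]}{i}"))
            return out
        return (mk(POSITIVE, n_pos, True), mk(HARD_NEGATIVE, n_hard, True),
                mk(EASY_NEGATIVE, n_easy, False))

    def test_60_20_20_counts_and_1_1_1_valtest(self, rng):
        pos, hard, easy = self._pools(rng)
        out = make_splits(pos, hard, easy, CurationConfig(seed=4))
        for split, n_pos in (("train", 60), ("val", 20), ("test", 20)):
            sub = split_of(out, split)
            assert sum(e.tier == POSITIVE for e in sub) == n_pos
        for split in ("val", "test"):
            sub = split_of(out, split)
            counts = {t: sum(e.tier == t for e in sub)
                      for t in (POSITIVE, HARD_NEGATIVE, EASY_NEGATIVE)}
            assert len(set(counts.values())) == 1    # 1:1:1

    def test_no_pair_leaks_across_splits(self, rng):
        pos, hard, easy = self._pools(rng)
        out = make_splits(pos, hard, easy, CurationConfig(seed=4))
        seen = {}
        for e in out:
            assert e.key not in seen or seen[e.key] == e.split
            seen.setdefault(e.key, e.split)
        keys_by_split = [
            {e.key for e in split_of(out, s)} for s in
            ("train", "val", "test")]
        assert not (keys_by_split[0] & keys_by_split[1])
        assert not (keys_by_split[0] & keys_by_split[2])
        assert not (keys_by_split[1] & keys_by_split[2])

    def test_empty_easy_pool_raises_shortfall(self, rng):
        pos, hard, _ = self._pools(rng)
        with pytest.raises(ValueError, match="easy"):
            make_splits(pos, hard, [], CurationConfig(seed=4))

    def test_remainder_goes_to_train(self, rng):
        pos, hard, easy = self._pools(rng, n_pos=101)
        out = make_splits(pos, hard, easy, CurationConfig(seed=4))
        assert sum(e.tier == POSITIVE and e.split == "train"
                   for e in out) == 61


def test_curated_world_satisfies_tier_invariants(tiny_examples):
    check_tier_invariants(tiny_examples)


def test_curated_world_representatives_unique(tiny_examples):
    combos = {}
    for e in tiny_examples:
        key = (e.tier, e.kinase_cluster, e.peptide_cluster)
        assert key not in combos, key
        combos[key] = e
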