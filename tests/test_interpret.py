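"""Explainability: partition attributions vs exhaustive Shapley, the
efficiency identity, null players, logos, motif decomposition, joint
UMAP projections."""
import numpy as np
import pytest

from phoskin.interpret import (AttributionVector, PartitionExplainer,
                               attribution_polarity_summary, balanced_tree,
                               build_pair_tree, exact_shapley, flat_tree,
                               information_content, joint_projection,
                               motif_decomposition, motif_recovery_rate,
                               owen_attributions, sequence_logo_matrix,
                               shap_attributions)
from phoskin.model import ModelConfig, MultitaskModel


def _random_set_function(n, seed):
    rng = np.random.default_rng(seed)
    W1 = rng.normal(size=(n, 16))
    b1 = rng.normal(size=16)
    W2 = rng.normal(size=16)

    def val(sets):
        X = np.array([[1.0 if i in s else 0.0 for i in range(n)]
                      for s in sets])
        return np.tanh(X @ W1 + b1) @ W2
    return val


class TestOwenAttributions:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_flat_tree_equals_exhaustive_shapley(self, seed):
        """With a root of singleton leaves the partition recursion must
        reproduce 2^n-enumeration Shapley values exactly."""
        n = 8
        val = _random_set_function(n, seed)
        phi, base, full = owen_attributions(val, n, flat_tree(n))
        oracle = exact_shapley(val, n)
        assert np.abs(phi - oracle).max() < 1e-6

    def test_efficiency_holds_for_binary_tree(self):
        n = 10
        val = _random_set_function(n, 3)
        phi, base, full = owen_attributions(
            val, n, balanced_tree(list(range(n))))
        assert base + phi.sum() == pytest.approx(full, abs=1e-10)

    def test_null_player_gets_zero(self):
        """A position the function never reads receives 0 attribution."""
        n = 6
        inner = _random_set_function(n - 1, 4)

        def val(sets):
            return inner([frozenset(i for i in s if i < n - 1)
                          for s in sets])
        for tree in (flat_tree(n), balanced_tree(list(range(n)))):
            phi, _, _ = owen_attributions(val, n, tree)
            assert abs(phi[n - 1]) < 1e-10

    def test_constant_function_gives_all_zeros(self):
        phi, base, full = owen_attributions(
            lambda sets: np.full(len(sets), 0.42), 7, flat_tree(7))
        assert np.allclose(phi, 0.0, atol=1e-12)
        assert base == full == pytest.approx(0.42)

    def test_block_leaves_share_credit_equally(self):
        n = 4

        def val(sets):     # additive: v(S) = sum of members
            return np.array([sum(s) + len(s) for s in sets], dtype=float)
        tree = balanced_tree(list(range(n)), leaf_size=2)
        phi, _, _ = owen_attributions(val, n, tree)
        assert phi[0] == pytest.approx(phi[1])     # leaf {0,1}
        assert phi[2] == pytest.approx(phi[3])


@pytest.fixture(scope="module")
def toy_model():
    return MultitaskModel(ModelConfig(d_model=16, n_layers=1, n_heads=2,
                                      d_ff=32, head_heads=2, seed=21))


class TestModelAttributions:
    def test_efficiency_on_real_model(self, toy_model):
        a = shap_attributions(toy_model, "ARRRAAASAAAAAAA", "ACDEFGHIKL",
                              kinase_block=4)
        assert a.base_value + a.peptide_part.sum() + a.kinase_part.sum() \
            == pytest.approx(a.prediction, abs=1e-4)
        assert a.peptide_part.shape == (15,)
        assert a.kinase_part.shape == (10,)

    def test_logit_output_mode(self, toy_model):
        a = shap_attributions(toy_model, "ARRRAAASAAAAAAA", "ACDEFGHIKL",
                              output="logit", kinase_block=4)
        assert np.isfinite(a.prediction)

    def test_constant_classifier_yields_zero_attributions(self):
        m = MultitaskModel(ModelConfig(d_model=16, n_layers=1, n_heads=2,
                                       d_ff=32, head_heads=2, seed=2))
        m.cls_out.weight.data[:] = 0.0
        m.cls_out.bias.data[:] = 0.0
        a = shap_attributions(m, "ARRRAAASAAAAAAA", "ACDEFGH",
                              kinase_block=4)
        assert np.allclose(a.peptide_part, 0.0, atol=1e-6)
        assert np.allclose(a.kinase_part, 0.0, atol=1e-6)
        assert a.base_value == pytest.approx(0.5, abs=1e-6)

    def test_efficiency_violation_raises(self):
        with pytest.raises(AssertionError, match="efficiency"):
            AttributionVector("x", base_value=0.0,
                              peptide_part=np.ones(15),
                              kinase_part=np.zeros(3), prediction=0.0)


class TestPolaritySummary:
    def _vec(self, pep_sum, kin_sum, L=4):
        pep = np.zeros(15)
        pep[0] = pep_sum
        kin = np.zeros(L)
        if L:
            kin[0] = kin_sum
        return AttributionVector("p", 0.1, pep, kin,
                                 0.1 + pep_sum + kin_sum)

    def test_all_positive_peptide_parts(self):
        s = attribution_polarity_summary([self._vec(0.2, -0.1),
                                          self._vec(0.3, -0.2)])
        assert s["peptide_positive_rate"] == 1.0
        assert s["kinase_positive_rate"] == 0.0

    def test_means_equal_bruteforce(self, rng):
        vecs = [self._vec(float(rng.normal()), float(rng.normal()))
                for _ in range(20)]
        s = attribution_polarity_summary(vecs)
        assert s["peptide_mean_sum"] == pytest.approx(
            np.mean([v.peptide_part.sum() for v in vecs]))
        assert s["kinase_mean_sum"] == pytest.approx(
            np.mean([v.kinase_part.sum() for v in vecs]))

    def test_absent_kinase_part_flagged(self):
        s = attribution_polarity_summary([self._vec(0.2, 0.0, L=0)])
        assert s["kinase_part"] == "absent"


class TestLogos:
    def test_single_peptide_unit_cells(self):
        logo = sequence_logo_matrix(["AAAAAAASAAAAAAA"])
        assert logo.shape == (15, 20)
        assert np.allclose(logo.sum(axis=1), 1.0)
        assert logo.max() == 1.0

    def test_columns_sum_to_one(self, rng):
        peps = []
        for _ in range(30):
            s = rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=15)
            s[7] = "S"
            peps.append("".join(s))
        logo = sequence_logo_matrix(peps)
        assert np.allclose(logo.sum(axis=1), 1.0)

    def test_uniform_peptides_have_near_zero_information(self, rng):
        peps = ["".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=15))
                for _ in range(4000)]
        logo = sequence_logo_matrix(peps)
        ic = information_content(logo)
        assert np.all(ic < 0.05)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            sequence_logo_matrix([])


def _attr(pep_part, peptide, kid="K1"):
    pep = np.asarray(pep_part, dtype=float)
    return AttributionVector(f"{kid}:{peptide}", 0.2, pep, np.zeros(0),
                             0.2 + pep.sum(), peptide=peptide,
                             kinase_id=kid)


class TestMotifDecomposition:
    def test_identical_vectors_single_cluster(self):
        v = np.zeros(15)
        v[4] = 0.5
        attrs = [_attr(v, "AAARAAASAAAAAAA") for _ in range(6)]
        clusters = motif_decomposition("K1", attrs)
        assert len(clusters) == 1
        assert len(clusters[0].member_pair_ids) == 6

    def test_two_planted_modes_separate(self, rng):
        """Vectors loading on -3 vs +2 must split into >= 2 clusters whose
        logos are dominated by the matching residues."""
        attrs = []
        for i in range(12):
            v = np.zeros(15)
            v += rng.normal(0, 0.01, 15)
            if i % 2:
                v[4] = 0.6      # offset -3
                pep = "AAAARAASAAAAAAA"
            else:
                v[9] = 0.6      # offset +2
                pep = "AAAAAAASADAAAAA"
            attrs.append(_attr(v, pep))
        clusters = motif_decomposition("K1", attrs)
        assert len(clusters) >= 2
        # every cluster is pure in this construction
        from phoskin.synthetic import AA_INDEX
        for c in clusters:
            r = c.logo[4, AA_INDEX["R"]]
            d = c.logo[9, AA_INDEX["D"]]
            assert max(r, d) == 1.0 and min(r, d) == 0.0

    def test_clusters_partition_the_input(self, rng):
        attrs = [_attr(rng.normal(0, 0.2, 15),
                       "AAAAAAASAAAAAAA") for _ in range(15)]
        clusters = motif_decomposition("K1", attrs)
        ids = [pid for c in clusters for pid in c.member_pair_ids]
        assert sorted(ids) == sorted(a.pair_id for a in attrs)

    def test_wrong_kinase_rejected(self):
        a = _attr(np.zeros(15), "AAAAAAASAAAAAAA", kid="K2")
        with pytest.raises(ValueError):
            motif_decomposition("K1", [a])


def test_motif_recovery_rate_counts_argmax_hits():
    good = _attr(np.eye(15)[4] * 0.7, "AAAARAASAAAAAAA")   # top at -3
    bad = _attr(np.eye(15)[0] * 0.7, "RAAAAAASAAAAAAA")    # top at -7
    rate = motif_recovery_rate({"K1": [good], "K2": [bad]},
                               {"K1": [-3], "K2": [-3]})
    assert rate == 0.5


class TestJointProjection:
    def test_shapes_determinism_and_cloud_separation(self):
        """Two well-separated embedding clouds stay separated after the
        joint 2-D reduction (positive silhouette on the known labels)."""
        rng = np.random.default_rng(8)
        n, d = 60, 12
        labels = np.repeat([0, 1], n // 2)
        def cloud(shift):
            base = rng.normal(0, 1, (n, d))
            base[labels == 1] += shift
            return base
        per_ckpt = {"epoch0": cloud(0.0), "epoch1": cloud(10.0)}
        ps1 = joint_projection(per_ckpt, seed=3, n_neighbors=10)
        ps2 = joint_projection(per_ckpt, seed=3, n_neighbors=10)
        for tag in per_ckpt:
            assert ps1.coords[tag].shape == (n, 2)
            assert np.allclose(ps1.coords[tag], ps2.coords[tag])
        from sklearn.metrics import silhouette_score
        assert silhouette_score(ps1.coords["epoch1"], labels) > 0

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError, match="n_neighbors"):
            joint_projection({"a": np.zeros((5, 4))}, n_neighbors=15)

    def test_mismatched_rows_rejected(self):
        with pytest.raises(ValueError):
            joint_projection({"a": np.zeros((5, 4)),
                              "b": np.zeros((6, 4))}, n_neighbors=3)
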