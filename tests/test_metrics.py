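import itertools
import math

import numpy as np
import pytest

import cellforge as cf
from cellforge.metrics import (MetricError, ari, gene_means, ilisi,
                               knn_discriminability, mmd,
                               mmd_permutation_test, nmi, pcc, qq_quantiles,
                               rf_discriminability, scc, wasserstein,
                               zscore_matrix)


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def _ari_pair_counting(a, b):
    """Brute-force ARI: classify every pair as concordant/discordant."""
    n = len(a)
    ss = sd = ds = dd = 0
    for i, j in itertools.combinations(range(n), 2):
        same_a, same_b = a[i] == a[j], b[i] == b[j]
        ss += same_a and same_b
        sd += same_a and not same_b
        ds += not same_a and same_b
        dd += not (same_a or same_b)
    total = math.comb(n, 2)
    ri = (ss + dd) / total
    # expected RI under the hypergeometric model
    sum_a = sum(math.comb(c, 2) for c in np.unique(a, return_counts=True)[1])
    sum_b = sum(math.comb(c, 2) for c in np.unique(b, return_counts=True)[1])
    expected = sum_a * sum_b / total
    max_index = (sum_a + sum_b) / 2
    if max_index == expected:
        return 0.0
    return (ss - expected) / (max_index - expected)


def _nmi_table_entropy(a, b):
    """NMI from the joint contingency table, natural logs."""
    a, b = np.asarray(a), np.asarray(b)
    n = len(a)
    ua, ub = np.unique(a), np.unique(b)
    p_ab = np.array([[np.mean((a == x) & (b == y)) for y in ub] for x in ua])
    p_a, p_b = p_ab.sum(1), p_ab.sum(0)
    h_a = -sum(p * math.log(p) for p in p_a if p > 0)
    h_b = -sum(p * math.log(p) for p in p_b if p > 0)
    i_ab = sum(p_ab[i, j] * math.log(p_ab[i, j] / (p_a[i] * p_b[j]))
               for i in range(len(ua)) for j in range(len(ub))
               if p_ab[i, j] > 0)
    if h_a + h_b == 0:
        return 1.0
    return 2 * i_ab / (h_a + h_b)


class TestGeneMeans:
    def test_single_cell_is_itself(self):
        assert gene_means(np.array([[1.0, 5.0]])).tolist() == [1.0, 5.0]

    def test_hand_mean(self):
        assert gene_means(np.array([[0.0, 2.0], [2.0, 0.0]])).tolist() == [1, 1]

    def test_constant_matrix(self):
        np.testing.assert_array_equal(gene_means(np.full((3, 4), 7.0)),
                                      np.full(4, 7.0))

    def test_empty_raises(self):
        with pytest.raises(MetricError):
            gene_means(np.empty((0, 3)))


class TestCorrelations:
    def test_scc_worked_example(self):
        # rank displacement (0,1,1,0): 1 - 6*2/(4*15) = 0.8
        assert scc([1, 2, 3, 4], [1, 3, 2, 4]) == pytest.approx(0.8)

    def test_scc_monotone_transform_gives_one(self):
        a = np.array([0.3, 1.2, 5.0, 9.9, 2.2])
        assert scc(a, np.exp(a)) == pytest.approx(1.0)
        assert scc(a, -a) == pytest.approx(-1.0)

    def test_scc_constant_vector_raises(self):
        with pytest.raises(MetricError):
            scc([1, 1, 1], [1, 2, 3])

    def test_pcc_affine_invariance(self):
        a = np.array([0.5, 2.0, 3.5])
        assert pcc(a, 2 * a + 3) == pytest.approx(1.0)
        assert pcc(a, -a) == pytest.approx(-1.0)

    def test_pcc_worked_example(self):
        # longhand: cov = 3/3, sd_a = sqrt(2/3)*..., r = 3/sqrt(2*4.6667)
        assert pcc([1, 2, 3], [1, 2, 4]) == pytest.approx(0.98198, abs=1e-5)

    def test_pcc_zero_variance_raises(self):
        with pytest.raises(MetricError):
            pcc([2, 2, 2], [1, 2, 3])


class TestMMD:
    def test_identical_samples_near_zero(self):
        x = np.random.default_rng(0).standard_normal((40, 5))
        assert abs(mmd(x, x, n_pcs=3, biased=True)) < 1e-9
        assert abs(mmd(x, x, n_pcs=3)) < 0.05

    def test_symmetry(self):
        rng = np.random.default_rng(1)
        a, b = rng.standard_normal((30, 4)), rng.standard_normal((25, 4)) + 1
        assert mmd(a, b, n_pcs=2) == pytest.approx(mmd(b, a, n_pcs=2), abs=1e-9)

    def test_separated_gaussians_exceed_permutation_null(self):
        rng = np.random.default_rng(2)
        a = rng.standard_normal((500, 1))
        b = rng.standard_normal((500, 1)) + 5.0
        obs, null = mmd_permutation_test(a, b, n_pcs=1, n_perms=200, seed=0)
        assert obs > np.percentile(null, 95)

    def test_n_pcs_validated(self):
        x = np.zeros((5, 3))
        with pytest.raises(MetricError):
            mmd(x, x, n_pcs=10)


class TestILISI:
    def test_far_separated_batches_give_zero(self):
        a = np.zeros((50, 2))
        b = np.full((50, 2), 100.0)
        assert ilisi(a, b, k_neighbors=10, n_pcs=2) == pytest.approx(0.0)

    def test_identical_clouds_mix_above_half(self):
        for seed in (0, 1, 2):
            rng = np.random.default_rng(seed)
            a = rng.standard_normal((500, 10))
            b = rng.standard_normal((500, 10))
            assert ilisi(a, b, k_neighbors=30, n_pcs=10) > 0.5

    def test_range_and_monotone_in_separation(self):
        rng = np.random.default_rng(3)
        base = rng.standard_normal((200, 4))
        vals = []
        for shift in (0.0, 2.0, 8.0):
            vals.append(ilisi(base, base + shift, k_neighbors=15, n_pcs=4))
        assert all(0 <= v <= 1 for v in vals)
        assert vals[0] > vals[1] > vals[2]

    def test_empty_batch_raises(self):
        with pytest.raises(MetricError):
            ilisi(np.empty((0, 2)), np.ones((5, 2)), k_neighbors=2, n_pcs=2)


class TestWasserstein:
    def test_identical_samples_zero(self):
        x = np.random.default_rng(0).standard_normal((30, 3))
        assert wasserstein(x, x, n_pcs=2) == pytest.approx(0.0, abs=1e-12)

    def test_point_mass_translation(self):
        a = np.zeros((50, 1))
        b = np.full((50, 1), 3.0)
        assert wasserstein(a, b, n_pcs=1) == pytest.approx(3.0, abs=1e-9)

    def test_shifted_uniforms(self):
        rng = np.random.default_rng(1)
        a = rng.uniform(0, 1, (4000, 1))
        b = rng.uniform(0, 1, (4000, 1)) + 0.5
        assert wasserstein(a, b, n_pcs=1) == pytest.approx(0.5, abs=0.05)


class TestQQ:
    def test_identical_columns_on_diagonal(self):
        x = np.random.default_rng(0).standard_normal(200)
        table = qq_quantiles(x, x, n_quantiles=21)
        np.testing.assert_allclose(table[:, 0], table[:, 1])

    def test_shift_moves_quantiles_by_shift(self):
        x = np.random.default_rng(1).standard_normal(500)
        table = qq_quantiles(x, x + 1.0, n_quantiles=11)
        np.testing.assert_allclose(table[:, 1] - table[:, 0], 1.0, atol=1e-9)

    def test_standard_normal_median_near_zero(self):
        x = np.random.default_rng(2).standard_normal(5000)
        z = zscore_matrix(x.reshape(-1, 1)).ravel()
        table = qq_quantiles(z, z, n_quantiles=3)
        assert abs(table[1, 0]) < 0.05

    def test_empty_raises(self):
        with pytest.raises(MetricError):
            qq_quantiles(np.array([]), np.array([1.0]))


class TestDiscriminability:
    def test_identical_distributions_near_chance(self):
        accs = []
        for seed in (0, 1, 2):
            rng = np.random.default_rng(seed)
            a = rng.standard_normal((500, 5))
            b = rng.standard_normal((500, 5))
            accs.append(rf_discriminability(a, b, seed=seed)["accuracy"])
        assert abs(np.mean(accs) - 0.5) < 0.1

    def test_separated_clouds_fully_classified(self):
        rng = np.random.default_rng(0)
        a = rng.standard_normal((100, 4))
        b = rng.standard_normal((100, 4)) + 50.0
        assert rf_discriminability(a, b, seed=0)["accuracy"] > 0.99
        assert knn_discriminability(a, b, seed=0)["accuracy"] > 0.99

    def test_confusion_matrix_identity(self):
        rng = np.random.default_rng(1)
        a = rng.standard_normal((60, 3))
        b = rng.standard_normal((60, 3)) + 0.5
        out = rf_discriminability(a, b, seed=1)
        c = out["confusion"]
        recomputed = (c["tp"] + c["tn"]) / (c["tp"] + c["tn"] + c["fp"] + c["fn"])
        assert recomputed == pytest.approx(out["accuracy"], abs=1e-9)

    def test_knn_identical_near_chance_and_split_honored(self):
        rng = np.random.default_rng(2)
        a = rng.standard_normal((500, 5))
        b = rng.standard_normal((500, 5))
        out = knn_discriminability(a, b, seed=0)
        assert abs(out["accuracy"] - 0.5) < 0.1
        assert out["n_test"] == round(0.3 * 1000)

    def test_too_few_cells_raises(self):
        with pytest.raises(MetricError):
            rf_discriminability(np.ones((3, 2)), np.ones((3, 2)), n_folds=5)


class TestClusteringAgreement:
    def test_identical_partitions(self):
        labels = np.array([0, 0, 1, 1, 2])
        assert ari(labels, labels) == pytest.approx(1.0)
        assert nmi(labels, labels) == pytest.approx(1.0)

    def test_ari_worked_example_crossed_pairs(self):
        # every within-pair of one partition is split by the other
        assert ari([1, 1, 2, 2], [1, 2, 1, 2]) == pytest.approx(-0.5)
        assert _ari_pair_counting([1, 1, 2, 2], [1, 2, 1, 2]) == \
            pytest.approx(-0.5)

    def test_label_renaming_invariance_and_symmetry(self):
        a = np.array([0, 0, 1, 1, 2, 2])
        b = np.array([5, 5, 9, 9, 7, 7])
        assert ari(a, b) == pytest.approx(1.0)
        c = np.array([0, 1, 1, 0, 2, 2])
        assert nmi(a, c) == pytest.approx(nmi(c, a))

    def test_agreement_with_oracles_on_small_partitions(self):
        """ARI/NMI match brute-force pair counting / table entropy on every
        pair of 3-label partitions of 5 items."""
        rng = np.random.default_rng(0)
        for _ in range(40):
            a = rng.integers(0, 3, size=5)
            b = rng.integers(0, 3, size=5)
            assert ari(a, b) == pytest.approx(_ari_pair_counting(a, b),
                                              abs=1e-9)
            assert nmi(a, b) == pytest.approx(_nmi_table_entropy(a, b),
                                              abs=1e-9)

    def test_independent_partitions_nmi_near_zero(self):
        rng = np.random.default_rng(1)
        a = rng.integers(0, 4, size=10_000)
        b = rng.integers(0, 4, size=10_000)
        assert nmi(a, b) < 0.01

    def test_length_mismatch(self):
        with pytest.raises(MetricError):
            ari([1, 2], [1, 2, 3])


class TestEvaluate:
    def test_self_comparison_is_perfect(self, toy_dataset):
        norm = cf.normalize(toy_dataset)
        rep = cf.evaluate(norm, norm, n_pcs=10, k_neighbors=5, seed=0)
        assert rep.scc == pytest.approx(1.0)
        assert rep.pcc == pytest.approx(1.0)
        assert abs(rep.mmd) < 0.05
        assert rep.wasserstein == pytest.approx(0.0, abs=1e-9)

    def test_deterministic_under_fixed_seed(self, toy_dataset):
        norm = cf.normalize(toy_dataset)
        other = cf.normalize(cf.inject_dropout(toy_dataset, 0.2, seed=1))
        a = cf.evaluate(norm, other, n_pcs=10, k_neighbors=5, seed=3)
        b = cf.evaluate(norm, other, n_pcs=10, k_neighbors=5, seed=3)
        assert a.to_dict() == b.to_dict()

    def test_report_ranges_on_random_pairs(self):
        rng = np.random.default_rng(0)
        for trial in range(3):
            a = np.abs(rng.standard_normal((60, 12)))
            b = np.abs(rng.standard_normal((60, 12))) * (1 + trial)
            ra = cf.NormalizedMatrix(a, [f"a{i}" for i in range(60)],
                                     [f"g{j}" for j in range(12)])
            rb = cf.NormalizedMatrix(b, [f"b{i}" for i in range(60)],
                                     [f"g{j}" for j in range(12)],
                                     {"cell_type": np.array(["x", "y"] * 30)})
            rep = cf.evaluate(ra, rb, n_pcs=5, k_neighbors=5, seed=trial)
            assert -1 <= rep.scc <= 1 and -1 <= rep.pcc <= 1
            assert 0 <= rep.ilisi <= 1
            assert 0 <= rep.rf_accuracy <= 1 and 0 <= rep.knn_accuracy <= 1
            assert rep.wasserstein >= 0
            assert -1 <= rep.ari <= 1 and 0 <= rep.nmi <= 1

    def test_gene_set_mismatch_raises(self, toy_dataset):
        norm = cf.normalize(toy_dataset)
        other = cf.NormalizedMatrix(norm.values, norm.cell_ids,
                                    [f"other_{g}" for g in norm.gene_ids])
        with pytest.raises(MetricError):
            cf.evaluate(norm, other)
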