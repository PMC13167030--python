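import numpy as np
import pytest

from stratws import (
    DegenerateShapeError,
    IndexSetError,
    LabelError,
    ParameterError,
    SizeError,
    gram_from_distances,
    hsic_biased,
    hsic_permutation_test,
    hsic_witness,
    median_heuristic,
    mmd2_biased,
    mmd_permutation_test,
    mmd_witness,
    periodic_gram,
    periodic_kernel,
    population_mmd_matrix,
    relative_mmd_test,
    stage_to_angle,
)


def _dist_from_upper(upper):
    n = int((1 + np.sqrt(1 + 8 * len(upper))) / 2)
    d = np.zeros((n, n))
    d[np.triu_indices(n, k=1)] = upper
    return d + d.T


def _random_psd_gram(rng, n):
    x = rng.normal(size=(n, 3))
    d = np.linalg.norm(x[:, None] - x[None], axis=2)
    return np.exp(-d)


class TestKernels:
    def test_median_heuristic_laplace(self):
        assert median_heuristic(_dist_from_upper([1.0, 2.0, 3.0])) == pytest.approx(0.5)
        d2 = np.array([[0.0, 2.0], [2.0, 0.0]])
        assert median_heuristic(d2) == pytest.approx(0.5)

    def test_median_heuristic_gaussian(self):
        d = _dist_from_upper([1.0, 2.0, 3.0])
        assert median_heuristic(d, family="gaussian") == pytest.approx(0.25)

    def test_degenerate_distances_rejected(self):
        with pytest.raises(DegenerateShapeError):
            median_heuristic(np.zeros((3, 3)))

    def test_gram_values(self):
        d = _dist_from_upper([1.0, 2.0, 3.0])
        g = gram_from_distances(d, family="laplace", gamma=1.0)
        assert g.values[0, 0] == 1.0
        assert g.values[0, 1] == pytest.approx(np.exp(-1.0))
        g2 = gram_from_distances(d, family="gaussian", gamma=0.5)
        assert g2.values[0, 2] == pytest.approx(np.exp(-2.0))
        with pytest.raises(ParameterError):
            gram_from_distances(d, gamma=-1.0)

    def test_periodic_kernel_properties(self):
        assert periodic_kernel(1.3, 1.3, gamma=2.0) == pytest.approx(1.0)
        assert periodic_kernel(0.0, np.pi, gamma=0.7) == pytest.approx(np.exp(-4 * 0.7))
        a, b = 0.4, 2.1
        assert periodic_kernel(a, b, 1.0) == pytest.approx(periodic_kernel(a + 2 * np.pi, b, 1.0))

    def test_stage_to_angle(self):
        assert stage_to_angle(0, 6) == 0.0
        assert stage_to_angle(3, 6) == pytest.approx(np.pi)
        assert stage_to_angle(5, 6) == pytest.approx(5 * np.pi / 3)
        with pytest.raises(ParameterError):
            stage_to_angle(6, 6)


class TestMMD:
    def test_identical_samples_zero(self):
        rng = np.random.default_rng(0)
        k_small = _random_psd_gram(rng, 4)
        k = np.tile(k_small, (2, 2))  # samples duplicated
        assert mmd2_biased(k, np.arange(4), np.arange(4, 8)) == pytest.approx(0.0, abs=1e-14)

    def test_singleton_collapse(self):
        c = 0.3
        k = np.array([[1.0, c], [c, 1.0]])
        assert mmd2_biased(k, [0], [1]) == pytest.approx(2 - 2 * c)

    def test_matches_double_loop_reference(self):
        rng = np.random.default_rng(1)
        k = _random_psd_gram(rng, 5)
        a, b = [0, 2, 4], [1, 3]
        ref = (
            sum(k[i, j] for i in a for j in a) / 9
            + sum(k[i, j] for i in b for j in b) / 4
            - 2 * sum(k[i, j] for i in a for j in b) / 6
        )
        assert mmd2_biased(k, a, b) == pytest.approx(ref, abs=1e-14)

    def test_overlapping_groups_rejected(self):
        k = np.eye(4)
        with pytest.raises(IndexSetError):
            mmd2_biased(k, [0, 1], [1, 2])

    def test_constant_kernel_p_one(self):
        k = np.ones((10, 10))
        labels = np.array([0] * 5 + [1] * 5)
        res = mmd_permutation_test(k, labels, n_perm=50, seed=0)
        assert res.statistic == pytest.approx(0.0, abs=1e-14)
        assert res.p_value == 1.0

    def test_p_value_floor(self):
        rng = np.random.default_rng(2)
        k = _random_psd_gram(rng, 12)
        labels = np.array([0] * 6 + [1] * 6)
        res = mmd_permutation_test(k, labels, n_perm=30, seed=3)
        assert res.p_value >= 1 / 31
        assert res.null_draws.size == 30

    def test_seed_reproducibility(self):
        rng = np.random.default_rng(4)
        k = _random_psd_gram(rng, 10)
        labels = np.array([0] * 5 + [1] * 5)
        r1 = mmd_permutation_test(k, labels, n_perm=40, seed=9)
        r2 = mmd_permutation_test(k, labels, n_perm=40, seed=9)
        np.testing.assert_array_equal(r1.null_draws, r2.null_draws)

    def test_bad_labels_rejected(self):
        k = np.eye(4)
        with pytest.raises(LabelError):
            mmd_permutation_test(k, np.zeros(4), n_perm=10, seed=0)


class TestRelativeMMD:
    def test_identical_xy_statistic_zero(self):
        rng = np.random.default_rng(5)
        k_small = _random_psd_gram(rng, 6)
        idx = np.arange(6)
        k = np.tile(k_small, (3, 3))
        res = relative_mmd_test(k, idx, idx + 6, idx + 12, n_perm=20, seed=0)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value >= 1 / 21

    def test_empty_group_rejected(self):
        k = np.eye(6)
        with pytest.raises(IndexSetError):
            relative_mmd_test(k, [], [0, 1], [2, 3], n_perm=5, seed=0)


class TestWitness:
    def test_identical_groups_zero_everywhere(self):
        rng = np.random.default_rng(6)
        k_small = _random_psd_gram(rng, 5)
        k = np.tile(k_small, (2, 2))
        h = mmd_witness(k, np.arange(5), np.arange(5, 10))
        np.testing.assert_allclose(h, 0.0, atol=1e-14)

    def test_mean_gap_equals_mmd2(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            n = int(rng.integers(4, 15))
            k = _random_psd_gram(rng, n)
            split = int(rng.integers(1, n))
            a, b = np.arange(split), np.arange(split, n)
            h = mmd_witness(k, a, b)
            gap = h[a].mean() - h[b].mean()
            assert gap == pytest.approx(mmd2_biased(k, a, b), abs=1e-12)

    def test_ranking_is_sorting_permutation(self):
        rng = np.random.default_rng(8)
        k = _random_psd_gram(rng, 8)
        a, b = np.arange(4), np.arange(4, 8)
        h = mmd_witness(k, a, b)
        order = np.argsort(-h[a])
        assert np.all(np.diff(h[a][order]) <= 0)


class TestHSIC:
    def test_constant_covariate_zero(self):
        rng = np.random.default_rng(9)
        k = _random_psd_gram(rng, 6)
        el = np.ones((6, 6))
        assert hsic_biased(k, el) == pytest.approx(0.0, abs=1e-14)

    def test_2x2_closed_form(self):
        a, b = 0.3, 0.8
        k = np.array([[1.0, a], [a, 1.0]])
        el = np.array([[1.0, b], [b, 1.0]])
        assert hsic_biased(k, el) == pytest.approx((1 - a) * (1 - b) / 4, abs=1e-14)

    def test_trace_formula_identity(self):
        rng = np.random.default_rng(10)
        for _ in range(20):
            n = int(rng.integers(2, 12))
            k = _random_psd_gram(rng, n)
            el = _random_psd_gram(rng, n)
            h = np.eye(n) - np.ones((n, n)) / n
            ref = np.trace(k @ h @ el @ h) / n**2
            assert hsic_biased(k, el) == pytest.approx(ref, abs=1e-12)

    def test_size_mismatch_rejected(self):
        with pytest.raises(SizeError):
            hsic_biased(np.eye(3), np.eye(4))

    def test_permutation_test_constant_covariate(self):
        rng = np.random.default_rng(11)
        k = _random_psd_gram(rng, 8)
        el = np.ones((8, 8))
        res = hsic_permutation_test(k, el, n_perm=30, seed=1)
        assert res.statistic == pytest.approx(0.0, abs=1e-14)
        assert res.p_value == 1.0

    def test_witness_identities(self):
        rng = np.random.default_rng(12)
        for _ in range(30):
            n = int(rng.integers(2, 12))
            k = _random_psd_gram(rng, n)
            el = _random_psd_gram(rng, n)
            w = hsic_witness(k, el)
            assert w.mean() == pytest.approx(hsic_biased(k, el), abs=1e-12)
            w_swapped = hsic_witness(el, k)
            assert w_swapped.mean() == pytest.approx(w.mean(), abs=1e-12)

    def test_witness_constant_covariate_zero(self):
        rng = np.random.default_rng(13)
        k = _random_psd_gram(rng, 6)
        w = hsic_witness(k, np.ones((6, 6)))
        np.testing.assert_allclose(w, 0.0, atol=1e-14)

    def test_out_of_sample_witness_matches_in_sample(self):
        rng = np.random.default_rng(14)
        k = _random_psd_gram(rng, 7)
        el = _random_psd_gram(rng, 7)
        w_in = hsic_witness(k, el)
        w_cross = hsic_witness(k, el, k_cross=k, l_cross=el)
        np.testing.assert_allclose(w_cross, w_in, atol=1e-12)


class TestPopulationMatrix:
    def test_duplicate_groups_zero_offdiagonal(self):
        rng = np.random.default_rng(15)
        k_small = _random_psd_gram(rng, 5)
        k = np.tile(k_small, (2, 2))
        m = population_mmd_matrix(k, [np.arange(5), np.arange(5, 10)])
        assert m[0, 1] == pytest.approx(0.0, abs=1e-7)
        np.testing.assert_array_equal(np.diag(m), [0.0, 0.0])

    def test_symmetric(self):
        rng = np.random.default_rng(16)
        k = _random_psd_gram(rng, 12)
        groups = [np.arange(4), np.arange(4, 8), np.arange(8, 12)]
        m = population_mmd_matrix(k, groups)
        np.testing.assert_array_equal(m, m.T)
        assert np.all(m >= 0)


def test_periodic_gram_median_bandwidth():
    angles = np.array([0.0, np.pi / 2, np.pi, 3 * np.pi / 2])
    g = periodic_gram(angles)
    assert np.all(np.diag(g.values) == 1.0)
    # squared chordal distances are {2, 2, 4, 2, 4, 2}; median 2 -> gamma 0.5
    assert g.gamma == pytest.approx(0.5)
    assert g.values[0, 2] == pytest.approx(np.exp(2 * 0.5 * (np.cos(np.pi) - 1)))
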