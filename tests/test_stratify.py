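import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stratws import (
    GridMismatchError,
    ParameterError,
    PointCloudShape,
    StratifiedEmbedding,
    embed_shape,
    normalize_to_unit_median,
    normalized_ranks,
    pairwise_distances,
    pairwise_stratified_distances,
    quantile_of_profile,
    ranking_scores,
    rigid_transform,
    stratified_distance,
    stratified_embedding,
)
from stratws.geometry import local_profile_matrix

from .conftest import random_shape, tiny_cloud

SQRT2 = np.sqrt(2.0)
# quantile of (1,1,sqrt2) at level 5/6: position 5/3 between the 2nd and 3rd
# order statistics
Q56 = 1.0 + (SQRT2 - 1.0) * (2.0 / 3.0)


class TestRankingScores:
    def test_line_means(self, collinear3):
        profs = local_profile_matrix(pairwise_distances(collinear3))
        np.testing.assert_allclose(ranking_scores(profs), [1.5, 1.0, 1.5])

    def test_unit_square_symmetry(self, unit_square):
        profs = local_profile_matrix(pairwise_distances(unit_square))
        np.testing.assert_allclose(ranking_scores(profs), np.full(4, (2 + SQRT2) / 3))

    def test_first_moment_matches_mean_ordering(self):
        shape = random_shape(seed=9, n_points=25)
        profs = local_profile_matrix(pairwise_distances(shape))
        by_mean = np.argsort(ranking_scores(profs, functional="mean"))
        by_m1 = np.argsort(ranking_scores(profs, functional="moments", k_moments=1))
        np.testing.assert_array_equal(by_mean, by_m1)

    def test_higher_moments_refine_not_contradict(self):
        shape = random_shape(seed=10, n_points=20)
        profs = local_profile_matrix(pairwise_distances(shape))
        mean_scores = ranking_scores(profs, functional="mean")
        lex = ranking_scores(profs, functional="moments", k_moments=3)
        # where means differ strictly, the lexicographic order agrees
        i, j = np.argmin(mean_scores), np.argmax(mean_scores)
        assert (mean_scores[i] < mean_scores[j]) == (lex[i] < lex[j])

    def test_bad_k_rejected(self):
        with pytest.raises(ParameterError):
            ranking_scores(np.ones((3, 2)), functional="moments", k_moments=0)


class TestNormalizedRanks:
    def test_midrank_with_tie(self):
        res = normalized_ranks(np.array([1.5, 1.0, 1.5]))
        np.testing.assert_allclose(res.ranks, [2.0 / 3, 0.5 / 3, 2.0 / 3])

    def test_full_tie(self):
        res = normalized_ranks(np.full(4, 3.3))
        np.testing.assert_allclose(res.ranks, [0.5, 0.5, 0.5, 0.5])

    def test_two_points(self):
        res = normalized_ranks(np.array([0.1, 0.9]))
        np.testing.assert_allclose(res.ranks, [0.25, 0.75])

    @given(st.integers(0, 10_000))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_ranks_open_interval_and_monotone(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.normal(size=rng.integers(2, 40))
        ranks = normalized_ranks(scores).ranks
        assert np.all((ranks > 0) & (ranks < 1))
        order = np.argsort(scores, kind="stable")
        assert np.all(np.diff(ranks[order]) >= 0)


class TestQuantileOfProfile:
    @pytest.mark.parametrize(
        "q,expected",
        [(0.5, 1.0), (5 / 6, Q56), (0.0, 1.0), (1.0, SQRT2)],
    )
    def test_corner_profile(self, q, expected):
        assert quantile_of_profile(np.array([1.0, 1.0, SQRT2]), q) == pytest.approx(
            expected, abs=1e-12
        )

    def test_out_of_range_rejected(self):
        with pytest.raises(ParameterError):
            quantile_of_profile(np.array([1.0, 2.0]), 1.2)


class TestStratifiedEmbedding:
    def test_unit_square_b1_q3(self, unit_square):
        e = stratified_embedding(pairwise_distances(unit_square), B=1, Q=3)
        np.testing.assert_allclose(e.phi, [[1.0, 1.0, Q56]], atol=1e-12)

    def test_rigid_copy_identical(self):
        shape = random_shape(seed=2, n_points=35)
        e0 = embed_shape(shape, B=10, Q=10)
        e1 = embed_shape(rigid_transform(shape, seed=5), B=10, Q=10)
        np.testing.assert_allclose(e1.phi, e0.phi, atol=1e-9)

    @pytest.mark.parametrize("n", [5, 6, 8])
    def test_bn_oracle_reproduces_sorted_profiles(self, n):
        """With B=N and exact order-statistic levels, rows are the raw
        sorted local profiles ordered by ranking score."""
        shape = tiny_cloud(seed=n, n=n)
        d = pairwise_distances(shape)
        profs = local_profile_matrix(d)
        scores = ranking_scores(profs)
        assert np.unique(scores).size == n  # distinct scores assumption
        levels = np.linspace(0.0, 1.0, n - 1)
        e = stratified_embedding(d, B=n, Q=n - 1, q_levels=levels)
        expected = profs[np.argsort(scores)]
        np.testing.assert_array_equal(e.phi, expected)

    def test_empty_bins_interpolated(self):
        # 26-point contour with B=100: most bins empty, all rows defined
        shape = random_shape(seed=3, n_points=26)
        e = embed_shape(shape, B=100, Q=30)
        assert np.all(np.isfinite(e.phi))
        assert np.all(np.diff(e.phi, axis=1) >= -1e-12)

    @given(st.integers(0, 10_000))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_rows_nondecreasing(self, seed):
        shape = random_shape(seed=seed, n_points=20 + seed % 30)
        e = embed_shape(shape, B=7, Q=13)
        assert np.all(np.diff(e.phi, axis=1) >= -1e-12)

    def test_point_order_permutation_invariance(self):
        shape = random_shape(seed=17, n_points=40)
        rng = np.random.default_rng(0)
        shuffled = PointCloudShape(shape.points[rng.permutation(40)])
        e0 = embed_shape(shape, B=10, Q=10)
        e1 = embed_shape(shuffled, B=10, Q=10)
        np.testing.assert_allclose(e1.phi, e0.phi, atol=1e-9)


class TestStratifiedDistance:
    def test_identical_embeddings_zero(self):
        e = embed_shape(random_shape(seed=1, n_points=20), B=5, Q=5)
        assert stratified_distance(e, e) == 0.0

    def test_constant_difference(self):
        q = np.linspace(0.05, 0.95, 4)
        e0 = StratifiedEmbedding(phi=np.zeros((3, 4)), q_grid=q)
        e1 = StratifiedEmbedding(phi=np.ones((3, 4)), q_grid=q)
        for p in (1.0, 2.0, 3.0):
            assert stratified_distance(e0, e1, p=p) == pytest.approx(1.0, abs=1e-15)

    def test_unit_vs_double_square(self, unit_square):
        double = PointCloudShape(unit_square.points * 2.0)
        e1 = stratified_embedding(pairwise_distances(unit_square), B=1, Q=3)
        e2 = stratified_embedding(pairwise_distances(double), B=1, Q=3)
        expected = np.sqrt((1.0 + 1.0 + Q56**2) / 3.0)
        assert stratified_distance(e1, e2, p=2.0) == pytest.approx(expected, abs=1e-12)

    def test_scale_invariance_after_normalization(self):
        shape = random_shape(seed=21, n_points=30)
        for c in (0.5, 3.0):
            scaled = PointCloudShape(shape.points * c)
            e1 = embed_shape(shape, B=8, Q=8, normalize=True)
            e2 = embed_shape(scaled, B=8, Q=8, normalize=True)
            assert stratified_distance(e1, e2) <= 1e-9

    def test_grid_mismatch_rejected(self):
        e1 = embed_shape(random_shape(seed=1, n_points=20), B=5, Q=5)
        e2 = embed_shape(random_shape(seed=2, n_points=20), B=5, Q=6)
        with pytest.raises(GridMismatchError):
            stratified_distance(e1, e2)


class TestPairwiseMatrix:
    def test_duplicated_shape_zero_matrix(self):
        shape = random_shape(seed=4, n_points=25)
        m = pairwise_stratified_distances([shape, shape], B=10, Q=10)
        np.testing.assert_allclose(m, np.zeros((2, 2)), atol=1e-12)

    def test_symmetric_and_triangle(self):
        shapes = [random_shape(seed=s, n_points=30) for s in range(5)]
        m = pairwise_stratified_distances(shapes, B=10, Q=10)
        np.testing.assert_array_equal(m, m.T)
        n = len(shapes)
        for i in range(n):
            for j in range(n):
                for k in range(n):
                    assert m[i, j] <= m[i, k] + m[k, j] + 1e-9
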