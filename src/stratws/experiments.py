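"""Validation experiments: calibration, power, consistency, runtime scaling.

These harnesses run the full pipeline (synthetic shapes -> embeddings ->
distances -> kernels -> permutation tests) under controlled generating
processes and report rates or curves. They back the package's statistical
claims:

* permutation tests are level-alpha under their nulls;
* tests have high power against fixed alternatives (circle vs ellipse,
  covariate-linked eccentricity);
* the estimated stratified distance between two independent samplings of
  the same continuous shape shrinks as the per-shape sample size grows
  (consistency);
* runtime grows near-quadratically in points per shape.

Problem sizes default to desk-scale settings (tens of shapes, 64-100
points per shape, B = Q = 20, 200 permutations) so a full validation run
completes in minutes on one core.
"""
from __future__ import annotations

import time

import numpy as np

from .kernstats import (
    gram_from_distances,
    hsic_permutation_test,
    mmd_permutation_test,
    periodic_gram,
    relative_mmd_test,
)
from .stratify import distances_from_embeddings, embed_shape, stratified_distance
from .synthdata import PopulationSpec, make_dependent_pairs, make_two_populations, sample_shape

__all__ = [
    "mmd_null_rejection_rate",
    "mmd_power",
    "relative_mmd_null_rejection_rate",
    "hsic_null_rejection_rate",
    "hsic_power",
    "consistency_curve",
    "runtime_scaling_slope",
]


def _trial_seeds(seed: int, n_trials: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n_trials)]


def _shape_gram(shapes, B, Q, normalize=True, p=2.0):
    emb = [embed_shape(s, B=B, Q=Q, normalize=normalize, p_exponent=p) for s in shapes]
    dist = distances_from_embeddings(emb, p=p)
    return gram_from_distances(dist, family="laplace")


def mmd_null_rejection_rate(
    n_trials: int = 200,
    n_shapes: int = 20,
    n_points: int = 64,
    n_perm: int = 200,
    B: int = 20,
    Q: int = 20,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Fraction of null MMD tests rejecting at level alpha.

    Both groups are drawn from the identical circle generator, so the
    rejection rate estimates the test's actual size.
    """
    rejections = 0
    for s in _trial_seeds(seed, n_trials):
        a, b = make_two_populations(
            null=True, effect=0.0, n_shapes=n_shapes, n_points=n_points, seed=s
        )
        gram = _shape_gram(a + b, B, Q)
        labels = np.array([0] * n_shapes + [1] * n_shapes)
        res = mmd_permutation_test(gram, labels, n_perm=n_perm, seed=s)
        rejections += res.p_value <= alpha
    return rejections / n_trials


def mmd_power(
    effect: float = 0.4,
    n_trials: int = 100,
    n_shapes: int = 30,
    n_points: int = 100,
    n_perm: int = 200,
    B: int = 20,
    Q: int = 20,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Rejection rate of the MMD test for circle vs ellipse populations."""
    rejections = 0
    for s in _trial_seeds(seed, n_trials):
        a, b = make_two_populations(
            null=False, effect=effect, n_shapes=n_shapes, n_points=n_points, seed=s
        )
        gram = _shape_gram(a + b, B, Q)
        labels = np.array([0] * n_shapes + [1] * n_shapes)
        res = mmd_permutation_test(gram, labels, n_perm=n_perm, seed=s)
        rejections += res.p_value <= alpha
    return rejections / n_trials


def relative_mmd_null_rejection_rate(
    n_trials: int = 200,
    n_shapes: int = 20,
    n_points: int = 64,
    n_perm: int = 200,
    B: int = 20,
    Q: int = 20,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Size of the relative MMD test under its null.

    X and Y are independent samples from one generator (circles), the
    reference Z comes from a different generator (ellipses), so the two
    distances to Z are equal in distribution.
    """
    rejections = 0
    for s in _trial_seeds(seed, n_trials):
        x, y = make_two_populations(
            null=True, effect=0.0, n_shapes=n_shapes, n_points=n_points, seed=s
        )
        _, z = make_two_populations(
            null=False, effect=0.4, n_shapes=n_shapes, n_points=n_points, seed=s + 1
        )
        gram = _shape_gram(x + y + z, B, Q)
        n = n_shapes
        res = relative_mmd_test(
            gram,
            np.arange(n),
            np.arange(n, 2 * n),
            np.arange(2 * n, 3 * n),
            n_perm=n_perm,
            seed=s,
        )
        rejections += res.p_value <= alpha
    return rejections / n_trials


def hsic_null_rejection_rate(
    n_trials: int = 200,
    n_pairs: int = 20,
    n_points: int = 64,
    n_perm: int = 200,
    B: int = 20,
    Q: int = 20,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Size of the HSIC test with shapes independent of the angle covariate."""
    rejections = 0
    for s in _trial_seeds(seed, n_trials):
        pairs = make_dependent_pairs(n=n_pairs, strength=0.0, seed=s, n_points=n_points)
        shapes = [p[0] for p in pairs]
        angles = np.array([p[1] for p in pairs])
        gram_k = _shape_gram(shapes, B, Q)
        gram_l = periodic_gram(angles)
        res = hsic_permutation_test(gram_k, gram_l, n_perm=n_perm, seed=s)
        rejections += res.p_value <= alpha
    return rejections / n_trials


def hsic_power(
    strength: float = 0.6,
    n_trials: int = 100,
    n_pairs: int = 60,
    n_points: int = 100,
    n_perm: int = 200,
    B: int = 20,
    Q: int = 20,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Rejection rate of HSIC when eccentricity tracks the angle covariate."""
    rejections = 0
    for s in _trial_seeds(seed, n_trials):
        pairs = make_dependent_pairs(n=n_pairs, strength=strength, seed=s, n_points=n_points)
        shapes = [p[0] for p in pairs]
        angles = np.array([p[1] for p in pairs])
        gram_k = _shape_gram(shapes, B, Q)
        gram_l = periodic_gram(angles)
        res = hsic_permutation_test(gram_k, gram_l, n_perm=n_perm, seed=s)
        rejections += res.p_value <= alpha
    return rejections / n_trials


def consistency_curve(
    sample_sizes=(50, 100, 200, 400),
    n_replicates: int = 20,
    B: int = 20,
    Q: int = 20,
    seed: int = 0,
) -> np.ndarray:
    """Median D_2 between two independent N-point samplings of a unit circle.

    As N grows the two samplings describe the same continuous shape ever
    better, so the median estimated self-distance should fall toward zero
    — the finite-sample face of estimator consistency.
    """
    seeds = _trial_seeds(seed, n_replicates * len(sample_sizes) * 2)
    medians = np.empty(len(sample_sizes))
    it = iter(seeds)
    for i, n in enumerate(sample_sizes):
        reps = np.empty(n_replicates)
        for r in range(n_replicates):
            shapes = []
            for _ in range(2):
                spec = PopulationSpec(
                    generator="circle", n_points=n, noise_sd=0.0, seed=next(it)
                )
                shapes.append(sample_shape(spec))
            e1 = embed_shape(shapes[0], B=B, Q=Q)
            e2 = embed_shape(shapes[1], B=B, Q=Q)
            reps[r] = stratified_distance(e1, e2, p=2.0)
        medians[i] = np.median(reps)
    return medians


def runtime_scaling_slope(
    sample_sizes=(100, 200, 400, 800),
    B: int = 100,
    Q: int = 100,
    n_repeats: int = 7,
    batch: int = 4,
    seed: int = 0,
) -> float:
    """Log-log slope of embedding + distance runtime against N.

    The pipeline cost is dominated by the N x N distance matrix and the
    N row sorts, so the slope should sit near 2 (an O(N^2 log N) cost).
    Each timing sample covers a batch of shape pairs to keep durations
    well above timer resolution; the best of ``n_repeats`` samples per N
    damps scheduler noise, and a warm-up pass absorbs one-time costs.
    """
    times = []
    for i, n in enumerate(sample_sizes):
        pairs = []
        for j in range(batch):
            s1 = sample_shape(
                PopulationSpec(generator="circle", n_points=n, noise_sd=0.02, seed=seed + 10 * i + j)
            )
            s2 = sample_shape(
                PopulationSpec(
                    generator="ellipse", n_points=n, noise_sd=0.02, seed=seed + 1000 + 10 * i + j
                )
            )
            pairs.append((s1, s2))

        def run():
            for s1, s2 in pairs:
                e1 = embed_shape(s1, B=B, Q=Q)
                e2 = embed_shape(s2, B=B, Q=Q)
                stratified_distance(e1, e2, p=2.0)

        run()  # warm-up
        best = np.inf
        for _ in range(n_repeats):
            t0 = time.perf_counter()
            run()
            best = min(best, time.perf_counter() - t0)
        times.append(best / batch)
    slope, _ = np.polyfit(np.log(np.asarray(sample_sizes, float)), np.log(times), 1)
    return float(slope)
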