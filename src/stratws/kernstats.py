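"""Kernels on shape space and population-level statistics.

The stratified Wasserstein distance is induced by an L^p norm on
embeddings, so Laplace and Gaussian kernels built from it are positive
definite and (when the embedding separates shapes) characteristic. That
licenses the standard kernel statistics implemented here:

* MMD — maximum mean discrepancy, the RKHS distance between mean
  embeddings of two shape populations (biased V-statistic estimator);
* relative MMD — which of two populations is closer to a reference;
* HSIC — Hilbert-Schmidt independence criterion between shapes and a
  paired covariate, (1/n^2) tr(KHLH);
* witness functions for both, which localize the samples driving a
  significant statistic.

Inference is by permutation: group labels (MMD) or covariate pairing
(HSIC) are shuffled, the statistic is recomputed, and the p-value is the
add-one-smoothed exceedance fraction, p = (1 + #{null >= obs})/(1 + P).
Ties count as exceedances, which is conservative.
"""
from __future__ import annotations

import numpy as np

from .errors import (
    DegenerateShapeError,
    IndexSetError,
    LabelError,
    ParameterError,
    SizeError,
)
from .types import KernelGram, TestResult

__all__ = [
    "median_heuristic",
    "gram_from_distances",
    "periodic_kernel",
    "periodic_gram",
    "stage_to_angle",
    "mmd2_biased",
    "mmd_permutation_test",
    "relative_mmd_test",
    "mmd_witness",
    "hsic_biased",
    "hsic_permutation_test",
    "hsic_witness",
    "population_mmd_matrix",
]


def _as_matrix(x) -> np.ndarray:
    if isinstance(x, KernelGram):
        return x.values
    return np.asarray(x, dtype=float)


def median_heuristic(distmat, family: str = "laplace") -> float:
    """Bandwidth gamma from the median pairwise distance of the sample.

    gamma = 1/median(d) for the Laplace kernel exp(-gamma d) and
    1/median(d^2) for the Gaussian exp(-gamma d^2); medians are over the
    strict upper triangle (all unordered pairs).
    """
    d = _as_matrix(distmat)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ParameterError("distance matrix must be square")
    upper = d[np.triu_indices(d.shape[0], k=1)]
    if upper.size == 0 or not np.any(upper > 0):
        raise DegenerateShapeError("all pairwise distances are zero")
    if family == "laplace":
        med = float(np.median(upper))
    elif family == "gaussian":
        med = float(np.median(upper**2))
    else:
        raise ParameterError(f"unknown kernel family {family!r}")
    if med <= 0:
        raise DegenerateShapeError("median pairwise distance is zero")
    return 1.0 / med


def gram_from_distances(distmat, family: str = "laplace", gamma: float | None = None) -> KernelGram:
    """Kernel Gram matrix from a pairwise distance matrix.

    laplace: k = exp(-gamma d); gaussian: k = exp(-gamma d^2). If gamma is
    None the median heuristic is applied. Entries lie in (0, 1] with unit
    diagonal.
    """
    d = _as_matrix(distmat)
    if gamma is None:
        gamma = median_heuristic(d, family=family)
    if gamma <= 0:
        raise ParameterError(f"gamma must be positive, got {gamma}")
    if family == "laplace":
        values = np.exp(-gamma * d)
    elif family == "gaussian":
        values = np.exp(-gamma * d**2)
    else:
        raise ParameterError(f"unknown kernel family {family!r}")
    np.fill_diagonal(values, 1.0)
    return KernelGram(values=values, family=family, gamma=float(gamma))


def periodic_kernel(y1, y2, gamma: float) -> np.ndarray | float:
    """Periodic (von Mises type) kernel on angles in radians.

    k(y1, y2) = exp(2*gamma*(cos(y1 - y2) - 1)), i.e. the Gaussian kernel
    applied to the chordal distance between the points (cos y, sin y) on
    the unit circle. Equals 1 iff the angles coincide mod 2*pi.
    """
    if gamma <= 0:
        raise ParameterError(f"gamma must be positive, got {gamma}")
    return np.exp(2.0 * gamma * (np.cos(np.asarray(y1, float) - np.asarray(y2, float)) - 1.0))


def periodic_gram(angles: np.ndarray, gamma: float | None = None) -> KernelGram:
    """Gram matrix of the periodic kernel over a vector of angles.

    If gamma is None it is set by the median heuristic on squared chordal
    distances between the circle embeddings [cos y, sin y].
    """
    theta = np.asarray(angles, dtype=float)
    diff = theta[:, None] - theta[None, :]
    if gamma is None:
        sq_chord = 2.0 * (1.0 - np.cos(diff))  # squared chordal distance
        upper = sq_chord[np.triu_indices(theta.size, k=1)]
        if upper.size == 0 or not np.any(upper > 0):
            raise DegenerateShapeError("all angles coincide; bandwidth undefined")
        gamma = 1.0 / float(np.median(upper))
    values = np.exp(2.0 * gamma * (np.cos(diff) - 1.0))
    return KernelGram(values=values, family="periodic", gamma=float(gamma))


def stage_to_angle(stage_index: int, n_stages: int) -> float:
    """Encode an ordered cyclic stage as an angle theta = 2*pi*stage/n."""
    if not 0 <= stage_index < n_stages:
        raise ParameterError(
            f"stage index must lie in [0, {n_stages}), got {stage_index}"
        )
    return 2.0 * np.pi * stage_index / n_stages


def _check_index_sets(n: int, *index_sets, disjoint: bool = True):
    out = []
    seen = set()
    for idx in index_sets:
        arr = np.asarray(idx, dtype=int)
        if arr.size == 0:
            raise IndexSetError("index set is empty")
        if arr.min() < 0 or arr.max() >= n:
            raise IndexSetError(f"index out of range for Gram of size {n}")
        if disjoint:
            s = set(arr.tolist())
            if len(s) != arr.size or s & seen:
                raise IndexSetError("index sets must be disjoint with unique entries")
            seen |= s
        out.append(arr)
    return out


def mmd2_biased(K, idxA, idxB) -> float:
    """Biased (V-statistic) squared MMD between two groups of a pooled Gram.

    (1/nA^2) sum_AA k + (1/nB^2) sum_BB k - (2/(nA nB)) sum_AB k, diagonal
    terms included. Nonnegative for any PSD kernel.
    """
    k = _as_matrix(K)
    a, b = _check_index_sets(k.shape[0], idxA, idxB)
    kaa = k[np.ix_(a, a)].sum() / (a.size**2)
    kbb = k[np.ix_(b, b)].sum() / (b.size**2)
    kab = k[np.ix_(a, b)].sum() / (a.size * b.size)
    return float(kaa + kbb - 2.0 * kab)


def _p_value(observed: float, null_draws: np.ndarray) -> float:
    return float((1 + np.sum(null_draws >= observed)) / (1 + null_draws.size))


def mmd_permutation_test(K, labels, n_perm: int = 1000, seed: int = 0) -> TestResult:
    """Two-sample MMD test with permutation of group labels.

    ``labels`` is a length-n vector with exactly two distinct values over
    the pooled sample the Gram matrix covers.
    """
    k = _as_matrix(K)
    labels = np.asarray(labels)
    if labels.size != k.shape[0]:
        raise LabelError("labels length must match Gram size")
    values = np.unique(labels)
    if values.size != 2:
        raise LabelError(f"need exactly 2 label values, found {values.size}")
    if n_perm < 1:
        raise ParameterError("n_perm must be >= 1")
    idx_a = np.flatnonzero(labels == values[0])
    idx_b = np.flatnonzero(labels == values[1])
    observed = mmd2_biased(k, idx_a, idx_b)
    rng = np.random.default_rng(seed)
    n = labels.size
    null = np.empty(n_perm)
    for t in range(n_perm):
        perm = rng.permutation(n)
        null[t] = mmd2_biased(k, perm[: idx_a.size], perm[idx_a.size :])
    return TestResult(
        statistic=observed,
        null_draws=null,
        p_value=_p_value(observed, null),
        n_permutations=n_perm,
        seed=seed,
    )


def relative_mmd_test(K, idxX, idxY, idxZ, n_perm: int = 1000, seed: int = 0) -> TestResult:
    """Relative MMD test: are X and Y equally distant from reference Z?

    Statistic T = |MMD^2(X,Z) - MMD^2(Y,Z)| (two-sided). The null pools X
    and Y, permutes their labels with Z fixed, and recomputes T.
    """
    k = _as_matrix(K)
    x, y, z = _check_index_sets(k.shape[0], idxX, idxY, idxZ)
    if n_perm < 1:
        raise ParameterError("n_perm must be >= 1")

    def stat(ix, iy):
        return abs(mmd2_biased(k, ix, z) - mmd2_biased(k, iy, z))

    observed = stat(x, y)
    pooled = np.concatenate([x, y])
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for t in range(n_perm):
        perm = rng.permutation(pooled.size)
        null[t] = stat(pooled[perm[: x.size]], pooled[perm[x.size :]])
    return TestResult(
        statistic=observed,
        null_draws=null,
        p_value=_p_value(observed, null),
        n_permutations=n_perm,
        seed=seed,
    )


def mmd_witness(K_rows, idxA, idxB) -> np.ndarray:
    """MMD witness h-hat evaluated at a set of shapes.

    ``K_rows`` holds kernel values from the pooled sample (rows) to the
    evaluation shapes (columns); passing the pooled Gram itself evaluates
    the witness on the sample (the default reporting mode). For each
    evaluation shape Z, h(Z) = mean_A k(., Z) - mean_B k(., Z); large
    positive values mark shapes typical of A and atypical of B.

    Identity: mean_A(h) - mean_B(h) over in-sample evaluation equals the
    biased MMD^2 exactly.
    """
    rows = _as_matrix(K_rows)
    a, b = _check_index_sets(rows.shape[0], idxA, idxB)
    return rows[a].mean(axis=0) - rows[b].mean(axis=0)


def _center(gram: np.ndarray) -> np.ndarray:
    """Doubly centered Gram: HKH with H = I - (1/n) 11^T."""
    row = gram.mean(axis=0, keepdims=True)
    col = gram.mean(axis=1, keepdims=True)
    return gram - row - col + gram.mean()


def hsic_biased(K, L) -> float:
    """Biased HSIC estimator (1/n^2) tr(KHLH).

    Computed as the Frobenius inner product of the doubly centered Gram
    matrices, which is algebraically identical and avoids forming H.
    """
    k = _as_matrix(K)
    el = _as_matrix(L)
    if k.shape != el.shape or k.shape[0] != k.shape[1]:
        raise SizeError(f"K and L must be same-size square matrices, got {k.shape} and {el.shape}")
    n = k.shape[0]
    if n < 2:
        raise SizeError("HSIC needs n >= 2")
    return float(np.sum(_center(k) * _center(el)) / n**2)


def hsic_permutation_test(K, L, n_perm: int = 1000, seed: int = 0) -> TestResult:
    """HSIC independence test, permuting the covariate pairing.

    Null draws apply a random simultaneous row/column permutation to L
    only, which breaks the shape-covariate pairing while preserving both
    marginals.
    """
    k = _as_matrix(K)
    el = _as_matrix(L)
    n = k.shape[0]
    if n < 3:
        raise SizeError("HSIC permutation test needs n >= 3")
    if n_perm < 1:
        raise ParameterError("n_perm must be >= 1")
    kc = _center(k)
    observed = float(np.sum(kc * _center(el)) / n**2)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    elc = _center(el)  # centering commutes with simultaneous permutation
    for t in range(n_perm):
        perm = rng.permutation(n)
        null[t] = float(np.sum(kc * elc[np.ix_(perm, perm)]) / n**2)
    return TestResult(
        statistic=observed,
        null_draws=null,
        p_value=_p_value(observed, null),
        n_permutations=n_perm,
        seed=seed,
    )


def hsic_witness(K, L, k_cross=None, l_cross=None) -> np.ndarray:
    """HSIC witness w-hat for shape-covariate pairs.

    w(s, y) = (1/n) sum_i k~(s, S_i) l~(y, Y_i), with k~ and l~ the
    empirically centered kernels. By default the witness is evaluated at
    the paired sample itself; to evaluate out of sample pass ``k_cross``
    (kernel rows from m evaluation shapes to the n sample shapes) and
    ``l_cross`` (likewise for covariates), both of shape (m, n).

    Positive values mark pairs supporting the observed dependence,
    negative values pairs opposing it. Identity: the mean of w over the
    paired sample equals the biased HSIC exactly.
    """
    k = _as_matrix(K)
    el = _as_matrix(L)
    n = k.shape[0]
    if k.shape != el.shape or n < 2:
        raise SizeError("K and L must be same-size square matrices with n >= 2")
    if (k_cross is None) != (l_cross is None):
        raise ParameterError("provide both k_cross and l_cross or neither")
    if k_cross is None:
        kc = _center(k)
        lc = _center(el)
    else:
        kx = np.asarray(k_cross, dtype=float)
        lx = np.asarray(l_cross, dtype=float)
        if kx.shape[1] != n or lx.shape[1] != n or kx.shape[0] != lx.shape[0]:
            raise SizeError("cross matrices must be (m, n) with matching m")
        kc = kx - kx.mean(axis=1, keepdims=True) - k.mean(axis=0, keepdims=True) + k.mean()
        lc = lx - lx.mean(axis=1, keepdims=True) - el.mean(axis=0, keepdims=True) + el.mean()
    return (kc * lc).mean(axis=1)


def population_mmd_matrix(K, groups) -> np.ndarray:
    """Matrix of MMD distances between >= 2 groups of a pooled sample.

    Entry (g, h) is sqrt(max(0, MMD^2(group g, group h))); the diagonal is
    exactly zero (a sample compared with itself). The result is a valid
    population-level distance matrix for MDS or clustering.
    """
    k = _as_matrix(K)
    idx = _check_index_sets(k.shape[0], *groups)
    if len(idx) < 2:
        raise LabelError("need at least 2 groups")
    g = len(idx)
    out = np.zeros((g, g))
    for i in range(g):
        for j in range(i + 1, g):
            val = np.sqrt(max(0.0, mmd2_biased(k, idx[i], idx[j])))
            out[i, j] = out[j, i] = val
    return out
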