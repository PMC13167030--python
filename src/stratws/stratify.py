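"""Stratified quantile embedding and the stratified Wasserstein distance.

The construction turns a shape's distance matrix into a fixed-size matrix
representative:

1. Each point's local distance distribution is summarized by a scalar
   ranking functional (default: its mean), which orders points from the
   shape's core to its periphery.
2. Scores are converted to normalized mid-ranks U in (0,1), a
   monotone-invariant, tie-stable coordinate along which the shape is
   stratified into B bins.
3. Within each bin, the quantile vectors of member points' local
   distance distributions (Q levels) are averaged, giving a B x Q matrix
   Phi-hat — a discretization of a function on the unit square.

The stratified Wasserstein distance D_p between two shapes is the
discretized L^p([0,1]^2) norm of the difference of their embeddings.
Because the embedding depends on the shape only through its distance
matrix, D_p is invariant to rigid motions and reflections by
construction, and to relabeling of points up to tie handling.
"""
from __future__ import annotations

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .errors import GridMismatchError, ParameterError
from .geometry import local_profile_matrix, pairwise_distances
from .shape_io import normalize_to_unit_median
from .types import (
    DistanceMatrix,
    LocalDistanceProfile,
    PointCloudShape,
    RankingResult,
    StratifiedEmbedding,
)

__all__ = [
    "ranking_scores",
    "normalized_ranks",
    "quantile_of_profile",
    "stratified_embedding",
    "embed_shape",
    "stratified_distance",
    "pairwise_stratified_distances",
]


def _as_profile_matrix(profiles) -> np.ndarray:
    if isinstance(profiles, np.ndarray):
        mat = np.asarray(profiles, dtype=float)
        if mat.ndim != 2:
            raise ParameterError("profile matrix must be 2D (N, m)")
        return mat
    rows = [
        p.sorted_distances if isinstance(p, LocalDistanceProfile) else np.asarray(p, float)
        for p in profiles
    ]
    if not rows:
        raise ParameterError("profile list must be nonempty")
    lengths = {r.size for r in rows}
    if len(lengths) != 1:
        raise ParameterError("all local profiles of one shape must have equal length")
    return np.vstack(rows)


def ranking_scores(profiles, functional: str = "mean", k_moments: int = 1) -> np.ndarray:
    """Scalar ranking score r_S(x_i) for each point's local profile.

    ``functional="mean"`` (the default) scores each point by the mean of
    its local distance distribution, which separates barycentric from
    peripheral points. ``functional="moments"`` orders points
    lexicographically by their first ``k_moments`` raw moments — a finer
    total order that breaks ties the mean cannot (useful on symmetric
    shapes) — and reports scores on the mean-moment scale so that
    ``k_moments=1`` reproduces the mean ordering.
    """
    mat = _as_profile_matrix(profiles)
    if functional == "mean":
        return mat.mean(axis=1)
    if functional == "moments":
        if k_moments < 1:
            raise ParameterError(f"moments functional needs k >= 1, got {k_moments}")
        n = mat.shape[0]
        moments = np.column_stack([(mat**j).mean(axis=1) for j in range(1, k_moments + 1)])
        # lexicographic mid-rank: primary key first moment, then higher
        keys = tuple(moments[:, j] for j in reversed(range(k_moments)))
        order = np.lexsort(keys)
        pos = np.empty(n)
        pos[order] = np.arange(1, n + 1)
        # exact row ties share their mid-rank position
        _, inv = np.unique(moments, axis=0, return_inverse=True)
        pos = np.array([pos[inv == g].mean() for g in inv])
        # map positions back to the first-moment scale (monotone rescale)
        return np.quantile(moments[:, 0], (pos - 0.5) / n)
    raise ParameterError(f"unknown ranking functional {functional!r}")


def _midranks(x: np.ndarray) -> np.ndarray:
    """1-based mid-ranks: tied values share the mean of their positions."""
    order = np.argsort(x, kind="mergesort")
    xs = x[order]
    n = x.size
    boundary = np.flatnonzero(np.concatenate(([True], xs[1:] != xs[:-1], [True])))
    start, end = boundary[:-1], boundary[1:]
    mid = (start + 1 + end) / 2.0
    ranks = np.empty(n)
    ranks[order] = np.repeat(mid, end - start)
    return ranks


def normalized_ranks(scores: np.ndarray) -> RankingResult:
    """Normalized mid-ranks U_i = (rank_i - 0.5)/N in (0,1).

    Ties receive the average of their occupied positions, so the result is
    invariant to point relabeling and stable under exactly tied scores.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.ndim != 1 or scores.size < 2:
        raise ParameterError("scores must be a 1D vector of length >= 2")
    if not np.all(np.isfinite(scores)):
        raise ParameterError("scores must be finite")
    ranks = (_midranks(scores) - 0.5) / scores.size
    return RankingResult(scores=scores, ranks=ranks)


def quantile_of_profile(profile, q: float) -> float:
    """Quantile of a sorted local profile by linear interpolation.

    The value at level q is read at fractional position (m-1)*q among the
    m sorted entries, interpolating linearly between order statistics.
    """
    if isinstance(profile, LocalDistanceProfile):
        values = profile.sorted_distances
    else:
        values = np.sort(np.asarray(profile, dtype=float))
    q = float(q)
    if not 0.0 <= q <= 1.0:
        raise ParameterError(f"quantile level must be in [0,1], got {q}")
    return float(np.quantile(values, q))


def _row_quantiles(sorted_rows: np.ndarray, q_grid: np.ndarray) -> np.ndarray:
    """Quantiles of pre-sorted rows by linear interpolation.

    The value at level q is read at fractional position (m-1)*q between
    order statistics — the same convention as np.quantile's default, but
    vectorized over rows without re-sorting. Positions within 1e-12 of an
    integer are snapped so exact order-statistic levels reproduce the
    entries bit for bit.
    """
    m = sorted_rows.shape[1]
    pos = (m - 1) * q_grid
    pos = np.where(np.abs(pos - np.round(pos)) < 1e-12, np.round(pos), pos)
    lo = np.floor(pos).astype(int)
    hi = np.minimum(lo + 1, m - 1)
    frac = pos - lo
    return sorted_rows[:, lo] * (1.0 - frac) + sorted_rows[:, hi] * frac


def _fill_empty_bins(phi: np.ndarray, counts: np.ndarray) -> np.ndarray:
    """Linear interpolation of empty bin rows against bin-center positions.

    Rows of empty bins are interpolated column-wise between the nearest
    nonempty bins; beyond the first/last nonempty bin the nearest row is
    extended (constant extrapolation). This keeps the embedding a
    discretization of a function on [0,1]^2 even when N < B.
    """
    b = phi.shape[0]
    nonempty = counts > 0
    if nonempty.all():
        return phi
    centers = (np.arange(b) + 0.5) / b
    src = centers[nonempty]
    vals = phi[nonempty]  # (S, Q)
    right = np.clip(np.searchsorted(src, centers), 0, src.size - 1)
    left = np.clip(right - 1, 0, src.size - 1)
    denom = src[right] - src[left]
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(denom > 0, (centers - src[left]) / np.where(denom > 0, denom, 1.0), 0.0)
    t = np.clip(t, 0.0, 1.0)
    out = vals[left] * (1.0 - t[:, None]) + vals[right] * t[:, None]
    out[nonempty] = phi[nonempty]
    return out


def stratified_embedding(
    D: DistanceMatrix,
    B: int = 100,
    Q: int = 100,
    functional: str = "mean",
    k_moments: int = 1,
    p_exponent: float = 2.0,
    q_levels: np.ndarray | None = None,
    normalized: bool = False,
) -> StratifiedEmbedding:
    """Stratified quantile embedding Phi-hat of one shape.

    Points are binned by normalized rank (point i lands in bin b iff
    U_i in ((b-1)/B, b/B]); each bin row is the unweighted mean of member
    points' quantile vectors evaluated at the midpoint grid
    q_j = (j - 0.5)/Q (or an explicit ``q_levels`` grid). Empty bins are
    filled by linear interpolation between nonempty neighbors.

    ``normalized`` is metadata recording whether the distance matrix was
    unit-median normalized upstream; it does not trigger normalization.
    """
    if B < 1 or Q < 1:
        raise ParameterError(f"need B >= 1 and Q >= 1, got B={B}, Q={Q}")
    if q_levels is None:
        q_grid = (np.arange(Q) + 0.5) / Q
    else:
        q_grid = np.asarray(q_levels, dtype=float)
        if q_grid.ndim != 1 or q_grid.size != Q:
            raise ParameterError("q_levels must be a 1D grid of length Q")
        if np.any(q_grid < 0) or np.any(q_grid > 1) or np.any(np.diff(q_grid) < 0):
            raise ParameterError("q_levels must be nondecreasing within [0,1]")

    profs = local_profile_matrix(D)  # (N, N-1), rows sorted
    scores = ranking_scores(profs, functional=functional, k_moments=k_moments)
    ranks = normalized_ranks(scores).ranks

    quant = _row_quantiles(profs, q_grid)  # (N, Q)

    # U in ((b-1)/B, b/B]  <=>  b = ceil(U * B); clip guards float edges
    bins = np.clip(np.ceil(ranks * B).astype(int) - 1, 0, B - 1)
    counts = np.bincount(bins, minlength=B).astype(float)
    order = np.argsort(bins, kind="stable")
    sorted_bins = bins[order]
    starts = np.flatnonzero(np.concatenate(([True], sorted_bins[1:] != sorted_bins[:-1])))
    sums = np.add.reduceat(quant[order], starts, axis=0)
    present = sorted_bins[starts]
    phi = np.zeros((B, Q))
    phi[present] = sums / counts[present, None]
    phi = _fill_empty_bins(phi, counts)

    return StratifiedEmbedding(
        phi=phi,
        q_grid=q_grid,
        p_exponent=p_exponent,
        normalized=normalized,
        functional=functional,
    )


def embed_shape(
    shape: PointCloudShape,
    B: int = 100,
    Q: int = 100,
    functional: str = "mean",
    k_moments: int = 1,
    metric: str = "euclidean",
    k: int | None = None,
    normalize: bool = False,
    p_exponent: float = 2.0,
) -> StratifiedEmbedding:
    """Pipeline convenience: distances -> (optional unit-median) -> embedding."""
    D = pairwise_distances(shape, metric=metric, k=k)
    if normalize:
        D = normalize_to_unit_median(D)
    return stratified_embedding(
        D,
        B=B,
        Q=Q,
        functional=functional,
        k_moments=k_moments,
        p_exponent=p_exponent,
        normalized=normalize,
    )


def _check_compatible(e1: StratifiedEmbedding, e2: StratifiedEmbedding) -> None:
    if e1.phi.shape != e2.phi.shape:
        raise GridMismatchError(
            f"embedding grids differ: {e1.phi.shape} vs {e2.phi.shape}"
        )
    if not np.allclose(e1.q_grid, e2.q_grid, rtol=0, atol=1e-12):
        raise GridMismatchError("embeddings use different quantile grids")


def stratified_distance(
    e1: StratifiedEmbedding, e2: StratifiedEmbedding, p: float = 2.0
) -> float:
    """Stratified Wasserstein distance D_p between two embedded shapes.

    D_p = ( (1/(B*Q)) * sum |Phi1 - Phi2|^p )^(1/p), the midpoint-rule
    discretization of the L^p norm on the unit square. The 1/(B*Q) weight
    makes values stable under grid refinement.
    """
    if p < 1:
        raise ParameterError(f"exponent p must be >= 1, got {p}")
    _check_compatible(e1, e2)
    diff = np.abs(e1.phi - e2.phi)
    return float(np.mean(diff**p) ** (1.0 / p))


def pairwise_stratified_distances(
    shapes: list[PointCloudShape],
    B: int = 100,
    Q: int = 100,
    p: float = 2.0,
    functional: str = "mean",
    metric: str = "euclidean",
    k: int | None = None,
    normalize: bool = False,
) -> np.ndarray:
    """Symmetric matrix of D_p over a list of shapes (each embedded once)."""
    if len(shapes) < 2:
        raise ParameterError("need at least 2 shapes")
    embeddings = [
        embed_shape(
            s, B=B, Q=Q, functional=functional, metric=metric, k=k,
            normalize=normalize, p_exponent=p,
        )
        for s in shapes
    ]
    return distances_from_embeddings(embeddings, p=p)


def distances_from_embeddings(
    embeddings: list[StratifiedEmbedding], p: float = 2.0
) -> np.ndarray:
    """D_p matrix from precomputed embeddings.

    D_p is the Minkowski-p distance between flattened embeddings scaled by
    (B*Q)^(-1/p), so the whole matrix comes from one vectorized pdist.
    """
    if p < 1:
        raise ParameterError(f"exponent p must be >= 1, got {p}")
    for e in embeddings[1:]:
        _check_compatible(embeddings[0], e)
    flat = np.vstack([e.phi.ravel() for e in embeddings])
    scale = flat.shape[1] ** (-1.0 / p)
    return squareform(pdist(flat, metric="minkowski", p=p)) * scale
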