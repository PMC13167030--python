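"""Reference distances: global Wasserstein and the GW second lower bound.

Both compare shapes through distributions of intrinsic distances, at
increasing strength:

* The global Wasserstein distance is the 1D p-Wasserstein distance
  between two shapes' global distance distributions. Fast
  (O(N^2 log N)), Hilbertian, but not injective — different shapes can
  share a global distance distribution.
* The second lower bound (SLB) of Gromov-Wasserstein couples points
  across shapes by the 1D Wasserstein cost between their *local*
  distance distributions, then takes the optimal coupling. With uniform
  equal-size marginals the transport polytope has permutation vertices,
  so the exact optimum is a linear assignment. SLB dominates the global
  Wasserstein distance (the global distribution is the uniform mixture
  of the local ones, and W_p^p is jointly convex).

Full Gromov-Wasserstein is deliberately not implemented here: exact GW is
believed NP-hard, and entropic approximations are a solver concern, not a
statistic of this package. ``slb`` and ``global_wasserstein`` serve as
benchmarks and as independent oracles in the test suite.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

from .errors import ParameterError, SizeError
from .geometry import local_profile_matrix
from .types import DistanceMatrix, GlobalDistanceProfile

__all__ = ["CouplingResult", "global_wasserstein", "slb"]


@dataclass
class CouplingResult:
    """Optimal coupling of an SLB computation.

    ``cost`` is the distance value; ``assignment[i]`` is the index in the
    second shape matched to point i of the first (a permutation).
    """

    cost: float
    assignment: np.ndarray


def _as_sorted(profile) -> np.ndarray:
    if isinstance(profile, GlobalDistanceProfile):
        return profile.sorted_distances
    arr = np.sort(np.asarray(profile, dtype=float))
    if arr.size < 1:
        raise ParameterError("profile must be nonempty")
    return arr


def wasserstein_1d_pth(a_sorted: np.ndarray, b_sorted: np.ndarray, p: float) -> float:
    """W_p^p between two empirical distributions given as sorted vectors.

    Equal sizes reduce to the elementwise mean of |a_i - b_i|^p. Unequal
    sizes are handled exactly: both quantile functions are piecewise
    constant with breakpoints at i/m, so |F1^-1 - F2^-1|^p is integrated
    on the merged breakpoint grid.
    """
    m1, m2 = a_sorted.size, b_sorted.size
    if m1 == m2:
        return float(np.mean(np.abs(a_sorted - b_sorted) ** p))
    grid = np.union1d(np.arange(1, m1 + 1) / m1, np.arange(1, m2 + 1) / m2)
    widths = np.diff(np.concatenate([[0.0], grid]))
    # F^-1 is right-continuous at 0: value a_i on ((i-1)/m, i/m]
    mids = grid - widths / 2  # interior points of each constant piece
    ia = np.minimum((mids * m1).astype(int), m1 - 1)
    ib = np.minimum((mids * m2).astype(int), m2 - 1)
    return float(np.sum(widths * np.abs(a_sorted[ia] - b_sorted[ib]) ** p))


def global_wasserstein(g1, g2, p: float = 2.0) -> float:
    """p-Wasserstein distance between two global distance distributions."""
    if p < 1:
        raise ParameterError(f"exponent p must be >= 1, got {p}")
    a = _as_sorted(g1)
    b = _as_sorted(g2)
    return wasserstein_1d_pth(a, b, p) ** (1.0 / p)


def slb(D1: DistanceMatrix, D2: DistanceMatrix, p: float = 2.0) -> CouplingResult:
    """Second lower bound of Gromov-Wasserstein between two shapes.

    Builds the N x N cost matrix M[i][j] = W_p^p(nu_{x_i}, nu_{y_j}) from
    local profiles (all of length N-1, so the elementwise formula applies)
    and solves the uniform-marginal optimal transport exactly by linear
    assignment. Returns the cost (1/N * matched cost sum)^(1/p) and the
    optimal permutation.

    Raises
    ------
    SizeError
        The shapes have different point counts (downsample first).
    """
    if p < 1:
        raise ParameterError(f"exponent p must be >= 1, got {p}")
    n1, n2 = D1.n_points, D2.n_points
    if n1 != n2:
        raise SizeError(f"SLB requires equal point counts, got {n1} and {n2}")
    prof1 = local_profile_matrix(D1)  # (N, N-1)
    prof2 = local_profile_matrix(D2)
    # |a_i - b_j|^p summed over sorted entries, all pairs at once
    diff = np.abs(prof1[:, None, :] - prof2[None, :, :]) ** p
    cost_matrix = diff.mean(axis=2)
    rows, cols = linear_sum_assignment(cost_matrix)
    assignment = np.empty(n1, dtype=int)
    assignment[rows] = cols
    cost = float((cost_matrix[rows, cols].mean()) ** (1.0 / p))
    return CouplingResult(cost=cost, assignment=assignment)
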