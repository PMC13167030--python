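"""Intrinsic distance matrices and local/global distance distributions.

A shape with uniform weights over its points is a metric measure space.
Its geometry enters the rest of the pipeline only through the pairwise
distance matrix C_ij = d_S(x_i, x_j) and the distance distributions
derived from it:

* the local distance distribution nu_x of a point x is the empirical
  distribution of distances from x to the other N-1 points;
* the global distance distribution nu_S pools all pairwise distances
  (each unordered pair once; the empirical quantile function is identical
  to the ordered-pair definition since every distance has the same
  multiplicity either way).
"""
from __future__ import annotations

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components, shortest_path
from scipy.spatial.distance import pdist, squareform

from .errors import ConnectivityError, ParameterError, SizeError
from .types import (
    DistanceMatrix,
    GlobalDistanceProfile,
    LocalDistanceProfile,
    PointCloudShape,
)

__all__ = [
    "pairwise_distances",
    "local_profiles",
    "local_profile_matrix",
    "global_profile",
    "export_distance_matrix",
]


def pairwise_distances(
    shape: PointCloudShape, metric: str = "euclidean", k: int | None = None
) -> DistanceMatrix:
    """Intrinsic distance matrix of a point cloud.

    ``metric="euclidean"`` gives straight-line ambient distances.
    ``metric="knn_geodesic"`` builds a k-nearest-neighbor graph with edges
    weighted by Euclidean length, symmetrized by edge union, and returns
    all-pairs shortest-path lengths — a discrete geodesic distance that
    follows the sampled surface rather than cutting through it.

    Raises
    ------
    ParameterError
        Unknown metric, or k outside [1, N-1] for the geodesic variant.
    ConnectivityError
        The kNN graph is disconnected (raise k).
    """
    pts = shape.points
    n = pts.shape[0]
    if n < 2:
        raise SizeError("distance matrix needs at least 2 points")
    if metric == "euclidean":
        values = squareform(pdist(pts))
        return DistanceMatrix(values=values, metric="euclidean")
    if metric != "knn_geodesic":
        raise ParameterError(f"unknown metric {metric!r}")
    if k is None:
        k = 10
    if not 1 <= k < n:
        raise ParameterError(f"knn_geodesic needs 1 <= k < N, got k={k}, N={n}")

    full = squareform(pdist(pts))
    # directed kNN edges: each point to its k nearest (excluding itself)
    order = np.argsort(full, axis=1, kind="stable")[:, 1 : k + 1]
    rows = np.repeat(np.arange(n), k)
    cols = order.ravel()
    weights = full[rows, cols]
    graph = csr_matrix((weights, (rows, cols)), shape=(n, n))
    graph = graph.maximum(graph.T)  # union symmetrization; weights coincide

    n_comp, _ = connected_components(graph, directed=False)
    if n_comp > 1:
        raise ConnectivityError(n_components=n_comp, k=k)
    values = shortest_path(graph, method="D", directed=False)
    return DistanceMatrix(values=values, metric="knn_geodesic", k=k)


def local_profile_matrix(D: DistanceMatrix) -> np.ndarray:
    """All N local profiles as an (N, N-1) array of row-sorted distances.

    Row i is the sorted distances from point i to the other points (the
    self-distance on the diagonal is excluded). This dense form is what the
    stratification code consumes.
    """
    v = D.values
    n = v.shape[0]
    off = v[~np.eye(n, dtype=bool)].reshape(n, n - 1)
    off.sort(axis=1)
    return off


def local_profiles(D: DistanceMatrix) -> list[LocalDistanceProfile]:
    """The N local distance distributions nu_{x_i} of a shape."""
    mat = local_profile_matrix(D)
    return [LocalDistanceProfile(sorted_distances=row) for row in mat]


def global_profile(D: DistanceMatrix) -> GlobalDistanceProfile:
    """The global distance distribution nu_S (upper triangle, sorted)."""
    upper = D.upper_triangle()
    return GlobalDistanceProfile(sorted_distances=np.sort(upper))


def export_distance_matrix(D: DistanceMatrix, path) -> None:
    """Dump the square matrix as CSV (debugging aid)."""
    np.savetxt(path, D.values, fmt="%.17g", delimiter=",")
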