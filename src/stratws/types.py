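"""Core containers shared across modules.

These are thin dataclasses around numpy arrays. They validate their
invariants on construction so downstream numeric code can assume
well-formed inputs.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError

__all__ = [
    "PointCloudShape",
    "BinaryImage",
    "DistanceMatrix",
    "LocalDistanceProfile",
    "GlobalDistanceProfile",
    "RankingResult",
    "StratifiedEmbedding",
    "KernelGram",
    "TestResult",
]


@dataclass
class PointCloudShape:
    """A shape as an unstructured point cloud in 2D or 3D.

    Points carry an implicit uniform probability measure: every point has
    weight 1/N. Coordinates are in arbitrary length units.

    Attributes
    ----------
    points : (N, D) float array, D in {2, 3}
    id : str
        Free-text identifier (file stem, cell id, ...).
    label : str or None
        Optional group / covariate tag.
    """

    points: np.ndarray
    id: str = ""
    label: str | None = None

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2:
            raise ParameterError("points must be a 2D array of shape (N, D)")
        n, d = pts.shape
        if d not in (2, 3):
            raise ParameterError(f"point dimension must be 2 or 3, got {d}")
        # a single point is allowed (e.g. the degenerate erosion of a
        # one-pixel mask); operations needing geometry check N >= 2 themselves
        if n < 1:
            raise ParameterError("a shape needs at least 1 point")
        if not np.all(np.isfinite(pts)):
            raise ParameterError("point coordinates must be finite")
        self.points = pts

    @property
    def n_points(self) -> int:
        return self.points.shape[0]

    @property
    def dim(self) -> int:
        return self.points.shape[1]


@dataclass
class BinaryImage:
    """A 2D mask or 3D volume of {0,1} values.

    Axis order is (row, col) in 2D and (plane, row, col) in 3D, with
    0-based integer indices. Any nonzero value counts as foreground.
    """

    array: np.ndarray

    def __post_init__(self):
        arr = np.asarray(self.array)
        if arr.ndim not in (2, 3):
            raise ParameterError(f"binary image must be 2D or 3D, got {arr.ndim}D")
        self.array = arr != 0

    @property
    def ndim(self) -> int:
        return self.array.ndim


@dataclass
class DistanceMatrix:
    """Symmetric N x N matrix of intrinsic distances within one shape.

    ``metric`` records how the distances were computed (``"euclidean"`` or
    ``"knn_geodesic"``); ``k`` is the neighbor count for the geodesic case.
    """

    values: np.ndarray
    metric: str = "euclidean"
    k: int | None = None

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ParameterError("distance matrix must be square")
        if not np.all(np.isfinite(v)):
            raise ParameterError("distance matrix entries must be finite")
        if np.any(v < 0):
            raise ParameterError("distances must be nonnegative")
        if not np.allclose(v, v.T, rtol=0, atol=1e-10):
            raise ParameterError("distance matrix must be symmetric")
        v = 0.5 * (v + v.T)
        np.fill_diagonal(v, 0.0)
        self.values = v

    @property
    def n_points(self) -> int:
        return self.values.shape[0]

    def upper_triangle(self) -> np.ndarray:
        """Strict upper-triangle entries, row-major."""
        iu = np.triu_indices(self.n_points, k=1)
        return self.values[iu]


@dataclass
class LocalDistanceProfile:
    """Sorted distances from one point to the N-1 others (nu_x)."""

    sorted_distances: np.ndarray

    def __post_init__(self):
        d = np.asarray(self.sorted_distances, dtype=float)
        if d.ndim != 1 or d.size < 1:
            raise ParameterError("profile must be a nonempty 1D vector")
        if np.any(np.diff(d) < 0):
            raise ParameterError("profile must be nondecreasing")
        self.sorted_distances = d

    def __len__(self) -> int:
        return self.sorted_distances.size


@dataclass
class GlobalDistanceProfile:
    """Sorted strict-upper-triangle distances of a shape (nu_S)."""

    sorted_distances: np.ndarray

    def __post_init__(self):
        d = np.asarray(self.sorted_distances, dtype=float)
        if d.ndim != 1 or d.size < 1:
            raise ParameterError("profile must be a nonempty 1D vector")
        if np.any(np.diff(d) < 0):
            raise ParameterError("profile must be nondecreasing")
        self.sorted_distances = d

    def __len__(self) -> int:
        return self.sorted_distances.size


@dataclass
class RankingResult:
    """Ranking-functional scores and normalized ranks for one shape.

    ``ranks`` are mid-ranks mapped to (0,1) via U_i = (rank_i - 0.5)/N, so
    tied scores share a rank and every value lies strictly inside (0,1).
    """

    scores: np.ndarray
    ranks: np.ndarray


@dataclass
class StratifiedEmbedding:
    """B x Q quantile matrix Phi-hat: the shape's Euclidean representative.

    Row b summarizes stratum b (points whose normalized rank falls in
    ((b-1)/B, b/B]) by the mean of their local-distance quantile vectors,
    evaluated on ``q_grid``. Rows are nondecreasing left to right.
    """

    phi: np.ndarray
    q_grid: np.ndarray
    p_exponent: float = 2.0
    normalized: bool = False
    functional: str = "mean"

    def __post_init__(self):
        phi = np.asarray(self.phi, dtype=float)
        if phi.ndim != 2:
            raise ParameterError("phi must be a B x Q matrix")
        if not np.all(np.isfinite(phi)) or np.any(phi < 0):
            raise ParameterError("phi entries must be finite and nonnegative")
        q = np.asarray(self.q_grid, dtype=float)
        if q.ndim != 1 or q.size != phi.shape[1]:
            raise ParameterError("q_grid length must equal the number of columns")
        self.phi = phi
        self.q_grid = q

    @property
    def n_bins(self) -> int:
        return self.phi.shape[0]

    @property
    def n_quantiles(self) -> int:
        return self.phi.shape[1]

    def flatten(self) -> np.ndarray:
        """Row-major vector of length B*Q for downstream embedding tools."""
        return self.phi.ravel().copy()


@dataclass
class KernelGram:
    """Symmetric kernel matrix over a sample of shapes (or covariates)."""

    values: np.ndarray
    family: str = "laplace"
    gamma: float = 1.0

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ParameterError("kernel Gram matrix must be square")
        self.values = 0.5 * (v + v.T)

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass
class TestResult:
    """Outcome of a permutation test.

    ``p_value`` uses add-one smoothing, p = (1 + #{null >= observed}) /
    (1 + n_permutations), so it is a valid finite-sample p-value and never
    smaller than 1/(n_permutations + 1).
    """

    statistic: float
    null_draws: np.ndarray = field(repr=False)
    p_value: float
    n_permutations: int
    seed: int

    def to_dict(self) -> dict:
        return {
            "statistic": float(self.statistic),
            "p_value": float(self.p_value),
            "n_permutations": int(self.n_permutations),
            "seed": int(self.seed),
        }
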