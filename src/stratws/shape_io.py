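"""Reading, writing and preprocessing of shapes.

Point clouds travel as delimited text tables (one point per row, 2 or 3
numeric columns, optional single header line). Segmentations arrive as
binary masks (PNG/TIFF) or volumes (multi-page TIFF) and are converted to
boundary/surface point clouds by a single binary-erosion step, the
standard recipe for turning filled segmentations into thin outlines.

Coordinate convention: pixel and voxel centers sit at integer coordinates,
mapped as (x, y) = (col, row) in 2D and (x, y, z) = (col, row, plane) in
3D. Only relative distances matter downstream, so any fixed convention
works; this one is fixed for reproducibility.
"""
from __future__ import annotations

import csv
import io
import os
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import (
    DegenerateShapeError,
    EmptyInputError,
    FormatError,
    SizeError,
)
from .types import BinaryImage, DistanceMatrix, PointCloudShape

__all__ = [
    "read_point_cloud",
    "write_point_cloud",
    "read_binary_image",
    "mask_to_boundary_points",
    "volume_to_surface_points",
    "downsample",
    "normalize_to_unit_median",
    "read_labels",
]


def _is_numeric_row(fields: list[str]) -> bool:
    try:
        for f in fields:
            float(f)
    except ValueError:
        return False
    return True


def read_point_cloud(
    path: str | os.PathLike | io.StringIO,
    delimiter: str = ",",
    id: str | None = None,
    label: str | None = None,
) -> PointCloudShape:
    """Read a point cloud from a delimited text table.

    Each row is one point with 2 or 3 numeric fields. A single non-numeric
    first row is treated as a header and skipped. Row order is preserved.

    Raises
    ------
    FormatError
        Inconsistent column counts or non-numeric data rows.
    SizeError
        Fewer than 2 data rows.
    """
    if isinstance(path, io.StringIO):
        handle = path
        shape_id = id or ""
    else:
        handle = open(path, "r", newline="")
        shape_id = id if id is not None else Path(path).stem
    try:
        rows = [r for r in csv.reader(handle, delimiter=delimiter) if r and any(f.strip() for f in r)]
    finally:
        if handle is not path:
            handle.close()

    if rows and not _is_numeric_row(rows[0]):
        rows = rows[1:]  # header line
    if len(rows) < 2:
        raise SizeError(f"point cloud needs at least 2 rows, found {len(rows)}")

    ncols = len(rows[0])
    if ncols not in (2, 3):
        raise FormatError(f"expected 2 or 3 coordinate columns, found {ncols}")
    pts = np.empty((len(rows), ncols), dtype=float)
    for i, row in enumerate(rows):
        if len(row) != ncols:
            raise FormatError(
                f"row {i} has {len(row)} fields, expected {ncols} (inconsistent columns)"
            )
        try:
            pts[i] = [float(f) for f in row]
        except ValueError as exc:
            raise FormatError(f"non-numeric value in data row {i}: {row}") from exc
    return PointCloudShape(points=pts, id=shape_id, label=label)


def write_point_cloud(shape: PointCloudShape, path: str | os.PathLike, delimiter: str = ",") -> None:
    """Write a point cloud as delimited text at full float precision.

    Uses %.17g so a write/read round trip reproduces coordinates exactly.
    """
    np.savetxt(path, shape.points, fmt="%.17g", delimiter=delimiter)


def read_binary_image(path: str | os.PathLike) -> BinaryImage:
    """Read a 2D mask (PNG/TIFF) or 3D volume (multi-page TIFF).

    Any nonzero value is foreground. Multi-channel 2D images are collapsed
    by "any channel nonzero".
    """
    suffix = Path(path).suffix.lower()
    if suffix in (".tif", ".tiff"):
        import tifffile

        arr = tifffile.imread(path)
    else:
        import imageio.v3 as iio

        arr = iio.imread(path)
    arr = np.asarray(arr)
    if arr.ndim == 3 and arr.shape[-1] in (3, 4) and suffix not in (".tif", ".tiff"):
        arr = arr.any(axis=-1)  # RGB(A) mask
    return BinaryImage(array=arr)


def _boundary_voxels(fg: np.ndarray) -> np.ndarray:
    """Foreground minus one binary erosion (cross-shaped structuring element).

    If erosion empties the mask (thin structures), all foreground elements
    are returned instead of failing.
    """
    structure = ndimage.generate_binary_structure(fg.ndim, 1)  # 4-/6-connected
    eroded = ndimage.binary_erosion(fg, structure=structure)
    boundary = fg & ~eroded
    if not boundary.any() or not eroded.any():
        boundary = fg
    return boundary


def mask_to_boundary_points(img: BinaryImage, id: str = "", label: str | None = None) -> PointCloudShape:
    """Boundary pixels of a 2D mask as a point cloud.

    The boundary is the set of foreground pixels removed by one 4-connected
    erosion step; coordinates are (x, y) = (col, row) at pixel centers.

    Raises
    ------
    EmptyInputError
        No foreground pixel.
    """
    if img.ndim != 2:
        raise FormatError(f"expected a 2D mask, got {img.ndim}D")
    fg = img.array
    if not fg.any():
        raise EmptyInputError("mask has no foreground pixels")
    rows, cols = np.nonzero(_boundary_voxels(fg))
    pts = np.column_stack([cols, rows]).astype(float)
    return PointCloudShape(points=pts, id=id, label=label)


def volume_to_surface_points(img: BinaryImage, id: str = "", label: str | None = None) -> PointCloudShape:
    """Surface voxels of a 3D volume as a point cloud.

    Exactly one 6-connected erosion iteration; returned points are the
    foreground voxels whose eroded value is 0, at (x, y, z) =
    (col, row, plane).

    Raises
    ------
    EmptyInputError
        No foreground voxel.
    """
    if img.ndim != 3:
        raise FormatError(f"expected a 3D volume, got {img.ndim}D")
    fg = img.array
    if not fg.any():
        raise EmptyInputError("volume has no foreground voxels")
    planes, rows, cols = np.nonzero(_boundary_voxels(fg))
    pts = np.column_stack([cols, rows, planes]).astype(float)
    return PointCloudShape(points=pts, id=id, label=label)


def downsample(shape: PointCloudShape, m: int, seed: int) -> PointCloudShape:
    """Uniform random subsample of m distinct points, reproducible by seed.

    Raises
    ------
    SizeError
        m > N or m < 2.
    """
    n = shape.n_points
    if m > n:
        raise SizeError(f"cannot downsample {n} points to {m}")
    if m < 2:
        raise SizeError(f"downsampled shape needs at least 2 points, got m={m}")
    rng = np.random.default_rng(seed)
    idx = rng.choice(n, size=m, replace=False)
    return PointCloudShape(points=shape.points[idx], id=shape.id, label=shape.label)


def normalize_to_unit_median(D: DistanceMatrix) -> DistanceMatrix:
    """Rescale a distance matrix so its median pairwise distance is 1.

    The median is taken over the strict upper triangle (each unordered pair
    once); for an even count it is the mean of the two central order
    statistics, which makes the operation idempotent.

    Raises
    ------
    DegenerateShapeError
        All off-diagonal distances are zero.
    """
    upper = D.upper_triangle()
    med = float(np.median(upper))
    if med <= 0:
        raise DegenerateShapeError("all pairwise distances are zero; cannot normalize")
    return DistanceMatrix(values=D.values / med, metric=D.metric, k=D.k)


def read_labels(path: str | os.PathLike) -> pd.DataFrame:
    """Read an id,label[,covariate] CSV table.

    Returns a DataFrame indexed by ``id`` with a ``label`` column and any
    further columns (e.g. a numeric covariate) preserved.
    """
    df = pd.read_csv(path, dtype={0: str})
    cols = [c.strip().lower() for c in df.columns]
    if "id" not in cols or "label" not in cols:
        raise FormatError(f"labels table must have 'id' and 'label' columns, found {list(df.columns)}")
    df.columns = cols
    return df.set_index("id")
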