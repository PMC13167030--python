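import numpy as np
import pytest

from stratws import PointCloudShape, PopulationSpec, sample_shape


@pytest.fixture
def unit_square() -> PointCloudShape:
    return PointCloudShape(np.array([[0, 0], [1, 0], [0, 1], [1, 1]], float), id="square")


@pytest.fixture
def collinear3() -> PointCloudShape:
    """Points 0, 1, 2 on a line."""
    return PointCloudShape(np.array([[0, 0], [1, 0], [2, 0]], float), id="line3")


def tiny_cloud(seed: int, n: int, dim: int = 2) -> PointCloudShape:
    """A bare random point cloud, for exhaustive-oracle tests at small N."""
    rng = np.random.default_rng(seed)
    return PointCloudShape(rng.random((n, dim)))


def random_shape(seed: int, n_points: int = 40, dim: int = 2) -> PointCloudShape:
    """A generic random synthetic shape, alternating generator families."""
    generators_2d = ("circle", "ellipse", "polygon", "tshape")
    generators_3d = ("ellipsoid3d", "dumbbell3d")
    pool = generators_2d if dim == 2 else generators_3d
    spec = PopulationSpec(
        generator=pool[seed % len(pool)],
        n_points=n_points,
        noise_sd=0.02,
        seed=seed,
    )
    return sample_shape(spec)
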