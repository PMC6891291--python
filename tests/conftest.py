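import numpy as np
import pytest

from bovimetry.cloud import PointCloud
from bovimetry.measure import MeasureConfig, reference_db_from_scenes
from bovimetry.synth import SceneConfig, generate_scene


@pytest.fixture(scope="session")
def default_scene():
    """One default synthetic scene with its ground truth."""
    return generate_scene(seed=1)


@pytest.fixture(scope="session")
def feature_db():
    """Feature database built from three held-out reference animals."""
    return reference_db_from_scenes([101, 102, 103])


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_cloud(rng):
    """A generic, asymmetric 1000-point cloud for oracle comparisons."""
    pts = rng.normal(size=(1000, 3)) * np.array([1.0, 0.5, 0.25])
    return PointCloud(pts)


def sphere_cloud(radius: float, n: int = 4000, seed: int = 0) -> PointCloud:
    rng = np.random.default_rng(seed)
    u = rng.normal(size=(n, 3))
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    return PointCloud(radius * u)


def cylinder_cloud(radius: float, length: float = 4.0, n: int = 4000,
                   seed: int = 0) -> PointCloud:
    rng = np.random.default_rng(seed)
    th = rng.uniform(0, 2 * np.pi, n)
    z = rng.uniform(-length / 2, length / 2, n)
    return PointCloud(np.column_stack([radius * np.cos(th),
                                       radius * np.sin(th), z]))


def plane_cloud(extent: float = 1.0, n: int = 2000, seed: int = 0) -> PointCloud:
    rng = np.random.default_rng(seed)
    xy = rng.uniform(-extent, extent, size=(n, 2))
    return PointCloud(np.column_stack([xy, np.zeros(n)]))
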