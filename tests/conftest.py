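import numpy as np
import pytest

from nnfdk import (
    ConeBeamGeometry,
    ProjectionStack,
    VoxelVolume,
    default_geometry,
)


@pytest.fixture(scope="session")
def geom8():
    return default_geometry(8, 6, cone_angle_deg=10.0)


@pytest.fixture(scope="session")
def geom16():
    return default_geometry(16, 12, cone_angle_deg=10.0)


@pytest.fixture(scope="session")
def geom32():
    return default_geometry(32, 24, cone_angle_deg=10.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def random_proj32(geom32):
    rng = np.random.default_rng(7)
    return ProjectionStack(rng.normal(size=geom32.projection_shape()), geom32)


def random_volume(geom, seed=0, scale=1.0):
    rng = np.random.default_rng(seed)
    return VoxelVolume(rng.random(geom.volume_shape()) * scale, geom.voxel_size)
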