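import numpy as np
import pytest
from shapely.geometry import box

from lidarhab.landscape import (
    LandscapeConfig,
    PointCloud,
    Zone,
    generate_landscape,
)


def random_cloud(rng, n=300, extent=20.0, ground_frac=0.4, zmax=15.0):
    """A small random classified cloud over a flat-ish terrain."""
    x = rng.uniform(0, extent, n)
    y = rng.uniform(0, extent, n)
    is_ground = rng.uniform(size=n) < ground_frac
    z = np.where(is_ground, rng.normal(0, 0.05, n), rng.uniform(0, zmax, n))
    cls = np.where(is_ground, 2, 3).astype(np.int16)
    return PointCloud(x, y, z, cls, bounds=(0, 0, extent, extent))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def herb_landscape():
    """Homogeneous herb layer (0-1 m, 8 pt/m² total) on constant ground."""
    cfg = LandscapeConfig(
        extent_m=(80.0, 80.0),
        water_channel=None,
        zones=[Zone("herb", box(0, 0, 80, 80), density=5.5, height_range=(0.1, 1.0))],
        ground_density=2.5,
        ground_elevation_model="constant",
        seed=42,
    )
    return generate_landscape(cfg)
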