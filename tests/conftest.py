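import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

from pondsight import FeatureSet, Polyline, RasterGrid, SimplePolygon


@pytest.fixture
def flat_dsm():
    return RasterGrid(0.0, 0.0, 1.0, np.zeros((60, 60)))


@pytest.fixture
def square_pond():
    return SimplePolygon("pond", [(20, 20), (30, 20), (30, 30), (20, 30), (20, 20)])


@pytest.fixture
def random_terrain():
    """Factory for smooth random terrain grids."""

    def make(seed: int, n: int = 64, cell_size: float = 1.0, relief: float = 6.0):
        rng = np.random.default_rng(seed)
        z = gaussian_filter(rng.uniform(0, 1, (n, n)), sigma=3)
        z = relief * (z - z.min()) / (z.max() - z.min())
        return RasterGrid(0.0, 0.0, cell_size, z)

    return make


@pytest.fixture
def straight_road():
    def make(y: float = 30.5, x0: float = 0.5, x1: float = 59.5, rid: str = "r0"):
        return FeatureSet("roads", [Polyline(rid, [(x0, y), (x1, y)])])

    return make
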