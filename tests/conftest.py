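import numpy as np
import pytest

from phyllonet.distmat import DistanceMatrix
from phyllonet.simulate import SimulationConfig, simulate_all


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def random_distance():
    """Factory for random valid distance matrices."""

    def make(n, seed=0):
        r = np.random.default_rng(seed)
        pts = r.normal(size=(n, 3))
        from scipy.spatial.distance import pdist, squareform

        return DistanceMatrix([f"s{i}" for i in range(n)], squareform(pdist(pts)))

    return make


@pytest.fixture(scope="session")
def small_bundle():
    """One reduced synthetic dataset shared by read-only tests."""
    return simulate_all(SimulationConfig.small(seed=7))


@pytest.fixture(scope="session")
def default_bundle():
    """One full-size synthetic dataset shared by read-only tests."""
    return simulate_all(SimulationConfig(seed=11))
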