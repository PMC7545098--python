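import numpy as np
import pytest

from roostsim.behaviour import FlightParams
from roostsim.environment import CavityField, build_hex_grid


@pytest.fixture(scope="session")
def grid():
    return build_hex_grid()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def flight():
    return FlightParams()


@pytest.fixture()
def small_field():
    """Ten cavities on a 300 m line near the plane centre, heights 4-13 m."""
    n = 10
    xy = np.column_stack([4400.0 + 30.0 * np.arange(n), np.full(n, 4500.0)])
    heights = np.linspace(4.0, 13.0, n)
    return CavityField(np.arange(n), xy, heights)
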