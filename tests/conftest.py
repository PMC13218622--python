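import numpy as np
import pytest

from shearclot.grid import build_channel_grid
from shearclot.kinetics import PlateletFields, default_params


@pytest.fixture
def small_grid():
    """2D 0.16 x 0.05 mm channel at 5 um resolution."""
    return build_channel_grid(0.16, 0.05, None, 0.005, mode_2d=True)


@pytest.fixture
def params():
    return default_params()


@pytest.fixture
def random_state(params):
    """Random positive platelet state on a flat array of cells (seeded)."""
    rng = np.random.default_rng(42)

    def make(n=1000, adp=True):
        arrs = [rng.uniform(0, 0.2 * params.P_max, n) for _ in range(7)]
        ADP = rng.uniform(0, 5.0, n) if adp else np.zeros(n)
        res = rng.uniform(0, 1.0, n)
        return PlateletFields(*arrs, ADP, res, params.P_max)

    return make
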