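import numpy as np
import pytest

from spikemap import RateCode, SimGrid


@pytest.fixture
def grid():
    return SimGrid(dt=0.01, t_window=3.0)


@pytest.fixture
def code(grid):
    return RateCode(f_max=10.0, grid=grid)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def periodic_steps(f: float, grid: SimGrid) -> np.ndarray:
    """Grid steps of a periodic train at ``f`` Hz (nearest-step snapping)."""
    n = int(np.floor(grid.t_window * f + 1e-9))
    times = np.arange(1, n + 1) / f
    idx = np.floor(times / grid.dt + 0.5 - 1e-12).astype(int) - 1
    return np.clip(idx, 0, grid.n_steps - 1)
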