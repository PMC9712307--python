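import numpy as np
import pytest

from symconn import FuncImage, make_symmetric_grid


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_grid():
    return make_symmetric_grid((8, 6, 6))


def make_image(data, tr_seconds=2.0):
    """Wrap a 4-D array in a FuncImage on a matching symmetric grid."""
    data = np.asarray(data, dtype=np.float64)
    grid = make_symmetric_grid(data.shape[:3])
    return FuncImage(data=data, grid=grid, tr_seconds=tr_seconds)


@pytest.fixture
def random_image(rng, small_grid):
    data = rng.standard_normal((*small_grid.dims, 60)) + 100.0
    return FuncImage(data=data, grid=small_grid, tr_seconds=2.0)
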