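import numpy as np
import pytest

from phasebench import make_bitmap_phantom, make_cell_phantom


@pytest.fixture(scope="session")
def small_bitmap():
    """12x12-bit bitmap with 10-px blocks in a 256^2 grid (fast end-to-end)."""
    return make_bitmap_phantom(n_bits_x=12, block_size=10, grid_size=256, seed=1)


@pytest.fixture(scope="session")
def tiny_bitmap_1to1():
    """10x10-bit bitmap at 1:1 pixel correspondence in a 64^2 grid."""
    return make_bitmap_phantom(n_bits_x=10, block_size=1, grid_size=64, seed=3)


@pytest.fixture(scope="session")
def small_cell():
    return make_cell_phantom(grid_size=128, max_phase=-1.0, seed=2)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
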