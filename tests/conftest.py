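import numpy as np
import pytest

import spheroidca as sc


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_grid():
    """9^3 lattice with a single central cell."""
    grid = sc.CellGrid(sc.LatticeConfig(dims=(9, 9, 9)))
    grid.set_cell((4, 4, 4), sc.Cell(phase=sc.Phase.G1))
    return grid


@pytest.fixture
def oxic_field():
    def make(grid, value=100.0):
        return sc.OxygenField(np.full(grid.dims, value, dtype=np.float64), grid.config)

    return make
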