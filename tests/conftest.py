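import numpy as np
import pytest

from phenouav.grids import ElevationGrid, GridTransform
from phenouav.simulate import SimulationConfig, simulate_genotype_truth, simulate_layout


def make_grid(values, cell=1.0, x0=0.0, y0=None, nodata=-9999.0):
    values = np.asarray(values, dtype=float)
    if y0 is None:
        y0 = values.shape[0] * cell
    return ElevationGrid(values, GridTransform(x0, y0, cell, -cell), nodata=nodata)


@pytest.fixture
def tiny_config():
    """A 12-genotype, 2-rep trial small enough for per-test rasterization."""
    return SimulationConfig(
        seed=7,
        n_genotypes=12,
        n_replicates=2,
        n_blocks_per_rep=3,
        cell_size_m=0.04,
        plot_length_m=2.0,
    )


@pytest.fixture
def tiny_layout(tiny_config):
    return simulate_layout(tiny_config)


@pytest.fixture
def tiny_truth(tiny_config, tiny_layout):
    return simulate_genotype_truth(tiny_config, tiny_layout)
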