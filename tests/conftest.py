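import numpy as np
import pytest

import fibwave as fw
from fibwave import synthetic_af as sa


@pytest.fixture(scope="session")
def grid16():
    """Full 16x16 lattice at 2.5 mm."""
    return fw.build_grid(16, 16, 2.5)


@pytest.fixture(scope="session")
def mapping_grid():
    """Default 249-electrode mapping array."""
    return fw.default_mapping_grid()


@pytest.fixture(scope="session")
def grid12():
    return fw.build_grid(12, 12, 2.5)


@pytest.fixture(scope="session")
def planar_series(grid12):
    """Noise-free planar wave entering from the left at 100 cm/s."""
    src = sa.Source("planar", sa.edge_sites(grid12, "left"), onset_ms=3.0)
    return sa.simulate_arrival_times(sa.Scenario(grid12, [src], speed_cm_s=100.0))


@pytest.fixture(scope="session")
def episode(mapping_grid):
    """Seeded compound AF episode on the 249-electrode array."""
    return sa.simulate_af_episode(mapping_grid, duration_ms=3000.0, seed=3)


def central_electrode(grid):
    d = np.linalg.norm(grid.coordinates - grid.coordinates.mean(axis=0), axis=1)
    return int(np.argmin(d))
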