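import numpy as np
import pytest

from olivenet import (LatticeGeometry, build_connectivity,
                      randomize_population, substreams)


@pytest.fixture(scope="session")
def small_geometry():
    return LatticeGeometry(dims=(5, 5, 2))


@pytest.fixture(scope="session")
def small_network(small_geometry):
    """50-cell lattice with default connectivity rules."""
    ss = substreams(11)
    cells = randomize_population(small_geometry.n_cells, seed=ss["cells"])
    net = build_connectivity(small_geometry, seed=ss["connectivity"])
    return cells, net


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
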