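import numpy as np
import pytest

import lcshic as L


@pytest.fixture(scope="session")
def genome():
    return L.generate_genome(seed=0)


@pytest.fixture(scope="session")
def bulk_control(genome):
    return L.simulate_bulk_hic(genome, L.SimulationParams(seed=0))


@pytest.fixture(scope="session")
def bulk_wgd(genome):
    return L.simulate_bulk_hic(genome, L.SimulationParams(seed=100, lcs_mix=0.5))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
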