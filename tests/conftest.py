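import numpy as np
import pytest

from degradome.simulate import SimConfig, simulate_counts, simulate_genome, simulate_panels


@pytest.fixture(scope="session")
def sim_cfg():
    return SimConfig(seed=7)


@pytest.fixture(scope="session")
def genome(sim_cfg):
    """(records, seqs, truth) for the shared synthetic genome."""
    return simulate_genome(sim_cfg)


@pytest.fixture(scope="session")
def panels(genome, sim_cfg):
    _, _, truth = genome
    return simulate_panels(truth, sim_cfg)


@pytest.fixture(scope="session")
def two_group(genome, sim_cfg):
    _, _, truth = genome
    return simulate_counts(truth, sim_cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
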