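import pytest

from paraloglens.synthetic import SimulationConfig, simulate


@pytest.fixture(scope="session")
def sim_default():
    """One default-condition simulated family shared across tests."""
    return simulate(SimulationConfig(seed=7))


@pytest.fixture(scope="session")
def sim_records(sim_default):
    return sim_default[0]


@pytest.fixture(scope="session")
def sim_alignment(sim_default):
    return sim_default[1]


@pytest.fixture(scope="session")
def sim_truth(sim_default):
    return sim_default[2]
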