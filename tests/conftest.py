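import numpy as np
import pytest

from polydup import simfamily


@pytest.fixture(scope="session")
def default_sim():
    """One simulated family under the default study conditions."""
    config = simfamily.SimConfig(seed=11)
    genome, truth = simfamily.evolve(config)
    return config, genome, truth


@pytest.fixture(scope="session")
def rendered_loci(default_sim):
    config, genome, _truth = default_sim
    return simfamily.render(genome, config)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260928)
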