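import pytest

from chromkit.simulate import SimulationConfig, make_genome


@pytest.fixture(scope="session")
def sim_config() -> SimulationConfig:
    return SimulationConfig(seed=7, n_genes=60, n_chroms=1, chrom_length=400_000)


@pytest.fixture(scope="session")
def genome(sim_config):
    """(annotation, sequences) for a small single-chromosome genome."""
    return make_genome(sim_config)


@pytest.fixture(scope="session")
def annotation(genome):
    return genome[0]
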