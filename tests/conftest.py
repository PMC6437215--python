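import pytest

from capfuse import simulate as sim


@pytest.fixture(scope="session")
def reference():
    """One fixed synthetic reference shared across tests (seed 11)."""
    cfg = sim.SimulationConfig(seed=11, n_genes=40)
    genome, genes = sim.simulate_reference(cfg)
    return genome, genes


@pytest.fixture(scope="session")
def genes(reference):
    return reference[1]


@pytest.fixture(scope="session")
def genome(reference):
    return reference[0]


@pytest.fixture(scope="session")
def panel(genes):
    return sim.panel_from_genes(genes)
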