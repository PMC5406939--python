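import pytest

from epiril import synthetic


@pytest.fixture(scope="session")
def config():
    return synthetic.SimulationConfig(seed=7)


@pytest.fixture(scope="session")
def parents(config):
    return synthetic.simulate_parents(config)


@pytest.fixture(scope="session")
def ril(config, parents):
    return synthetic.simulate_ril(config, parents, ril_id=1)


@pytest.fixture(scope="session")
def merged_rep1(ril):
    from epiril import cg
    return cg.merge_strand_table(ril.rep1)
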