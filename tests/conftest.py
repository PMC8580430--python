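import numpy as np
import pytest
from hypothesis import settings

from trnacoadapt.genetic_code import SENSE_ANTICODONS
from trnacoadapt.synthetic_data import SimulationConfig, write_bundle
from trnacoadapt.trna_inventory import TrnaCensus

settings.register_profile("ci", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("ci")


def make_census(copies, species="test"):
    """Census from a sparse {anticodon: copies} dict, zeros elsewhere."""
    t = {a: 0 for a in sorted(SENSE_ANTICODONS)}
    t.update(copies)
    return TrnaCensus(t=t, species=species)


@pytest.fixture
def census_factory():
    return make_census


@pytest.fixture
def rng():
    return np.random.default_rng(7)


@pytest.fixture(scope="session")
def sea_cucumber_bundle(tmp_path_factory):
    """A small sea cucumber-like bundle shared across tests."""
    outdir = tmp_path_factory.mktemp("bundle")
    config = SimulationConfig.sea_cucumber(seed=7, n_genes=60)
    return config, write_bundle(config, outdir)
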