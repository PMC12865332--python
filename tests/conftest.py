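import numpy as np
import pytest

from screpurpose import SimConfig, gen_drug_library, gen_sc_dataset


@pytest.fixture(scope="session")
def config():
    return SimConfig(seed=0)


@pytest.fixture(scope="session")
def sc_bundle(config):
    """One default synthetic single-cell dataset with its planted truth."""
    return gen_sc_dataset(config)


@pytest.fixture(scope="session")
def library_bundle(config, sc_bundle):
    _, truth = sc_bundle
    return gen_drug_library(config, truth), truth


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
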