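import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import yieldparts as yp

settings.register_profile(
    "ci", deadline=None, max_examples=50, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_config():
    return yp.SimConfig(seed=11)


@pytest.fixture(scope="session")
def noiseless_records(default_config):
    records, truth = yp.simulate_trait_table(default_config.noiseless())
    return records, truth


@pytest.fixture(scope="session")
def noisy_dataset(default_config):
    records, truth = yp.simulate_trait_table(default_config)
    return records, truth


@pytest.fixture(scope="session")
def tree():
    return yp.make_tree()


@pytest.fixture(scope="session")
def species_summary(noisy_dataset):
    records, _ = noisy_dataset
    comp = yp.components_frame(records)
    return yp.species_means(comp, scale="analysis")


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
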