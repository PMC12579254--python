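import numpy as np
import pytest

from mcpmap.cohort_synth import SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_config():
    return SimConfig(n_studies=2, samples_per_arm=12, n_genes=400, seed=11)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return simulate_cohort(small_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260929)
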