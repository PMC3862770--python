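import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import genassoc_meta as gm

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def bundled_records():
    return gm.load_bundled_cohort()


@pytest.fixture(scope="session")
def sim_cohort():
    """20 synthetic genotype-complete studies, fixed seed."""
    return gm.simulate_studies(gm.SimulationConfig(k_studies=20, seed=7))


@pytest.fixture(scope="session")
def allele_estimates(sim_cohort):
    ests, skipped = gm.effects_from_records(sim_cohort, gm.GeneticModel.ALLELE)
    assert not skipped
    return ests


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
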