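import numpy as np
import pytest
from hypothesis import settings

from cognet import GeneratorConfig, generate_cohort, make_atlas_fixture

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def atlas():
    return make_atlas_fixture(seed=0)


@pytest.fixture(scope="session")
def default_cohort():
    """One study-sized cohort with the asymmetric preset, shared across tests."""
    return generate_cohort(GeneratorConfig(seed=7))


@pytest.fixture(scope="session")
def large_patient_cohort():
    """n=200 patients under the default asymmetric preset."""
    return generate_cohort(GeneratorConfig(seed=11, n_patients=200))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
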