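import numpy as np
import pytest

from thirdvar.datamodel import ModelSpec
from thirdvar.synthetic import SyntheticParams, generate_cohort, load_fixture_cohort


@pytest.fixture(scope="session")
def fixture_cohort():
    """Bundled n=500 cohort (fixed seed)."""
    return load_fixture_cohort()


@pytest.fixture(scope="session")
def default_params():
    return SyntheticParams(n=2000, seed=101)


@pytest.fixture(scope="session")
def default_cohort(default_params):
    return generate_cohort(default_params)


@pytest.fixture
def dual_spec():
    return ModelSpec()


@pytest.fixture
def bmi_spec():
    return ModelSpec(third_variables=("bmi",))


@pytest.fixture
def rng():
    return np.random.default_rng(42)
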