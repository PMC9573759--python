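import numpy as np
import pandas as pd
import pytest
from hypothesis import settings, HealthCheck

from spoturine.synthetic_data import SyntheticParams, generate_cohort, make_fixture

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def tiny_cohort() -> pd.DataFrame:
    return make_fixture("tiny")


@pytest.fixture(scope="session")
def perfect_cohort() -> pd.DataFrame:
    return make_fixture("perfect_agreement")


@pytest.fixture(scope="session")
def qc_violations_cohort() -> pd.DataFrame:
    return make_fixture("qc_violations")


@pytest.fixture(scope="session")
def medium_cohort() -> pd.DataFrame:
    """Clean synthetic cohort reused across modules (n = 2000, fixed seed)."""
    return generate_cohort(SyntheticParams(n=2000), seed=42).records


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260927)
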