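import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from dfnc.preprocess import condition_timecourse
from dfnc.states import cluster_windows
from dfnc.synthetic import CohortConfig, generate_cohort
from dfnc.windows import windowed_fnc

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_cohort():
    """An 8-subject default-condition cohort shared across tests."""
    return generate_cohort(CohortConfig(n_subjects=8, seed=7))


@pytest.fixture(scope="session")
def conditioned(small_cohort):
    return [condition_timecourse(tc) for tc in small_cohort.subjects]


@pytest.fixture(scope="session")
def series_list(conditioned):
    return [windowed_fnc(tc) for tc in conditioned]


@pytest.fixture(scope="session")
def partition(series_list):
    return cluster_windows(series_list, k=4, seed=42)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
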