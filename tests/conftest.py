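import numpy as np
import pytest

from radconfound import QuadraticLogHazard, ScenarioConfig, WeibullHazard


@pytest.fixture(scope="session")
def cancer_hazard():
    return WeibullHazard(shape=6.086609, scale=75.992411)


@pytest.fixture(scope="session")
def noncancer_hazard():
    return QuadraticLogHazard(curvature=0.001022, shift=0.05311, intercept=-7.221)


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture
def small_config():
    """A default-mechanism scenario small enough for fast unit tests."""
    return ScenarioConfig(cohort_size=2000, n_reps=2, seed=424242)
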