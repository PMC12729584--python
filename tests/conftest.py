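import numpy as np
import pytest

from gefc.signal_features import extract_feature_matrix
from gefc.simulate import SimulationConfig, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """The default 14-patient synthetic cohort, seed 1."""
    return generate_cohort(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def ex0_matrix(default_cohort):
    """Windowed 87-column feature matrix for the resting-tremor exercise."""
    sessions = [s for s in default_cohort.sessions if s.exercise == 0]
    return extract_feature_matrix(sessions)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
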