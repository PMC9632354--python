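import numpy as np
import pytest

from drowse.synth import SubjectProfile, simulate_session


@pytest.fixture(scope="session")
def profile():
    return SubjectProfile()


@pytest.fixture(scope="session")
def awake_session(profile):
    """Ten minutes of alert driving at 15 fps."""
    return simulate_session(profile, "awake", 600.0, 15.0, seed=1)


@pytest.fixture(scope="session")
def fatigued_session(profile):
    """Ten minutes of fatigued driving, matched seed."""
    return simulate_session(profile, "fatigued", 600.0, 15.0, seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
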