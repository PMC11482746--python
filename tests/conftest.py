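import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import medoc as m

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def thermo():
    return m.DEFAULT_THERMO


@pytest.fixture(scope="session")
def zero_db():
    """Window-0 database with no couplings: every site titrates independently."""
    return m.generate_synthetic_db(window=0, coupling_strength=0.0, neutral_sigma=0.0, seed=0)


@pytest.fixture(scope="session")
def flat_db():
    """Window-2 database whose pair terms are all exactly zero."""
    return m.generate_synthetic_db(window=2, coupling_strength=0.0, neutral_sigma=0.0, seed=0)


@pytest.fixture(scope="session")
def coupled_db():
    """Window-3 screened-electrostatics database with default couplings."""
    return m.generate_synthetic_db(window=3, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240101)
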