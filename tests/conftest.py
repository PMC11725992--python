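import numpy as np
import pytest

import seradapt as sa
from seradapt.linear import LinearComponent, LinearParams


@pytest.fixture(scope="session")
def design():
    return sa.SessionDesign()


@pytest.fixture(scope="session")
def profile(design):
    return sa.sample_participant("A", design, seed=101)


@pytest.fixture(scope="session")
def session_events(profile, design):
    return sa.generate_session(profile, design, seed=102)


@pytest.fixture(scope="session")
def toy_cohort():
    """20-event toy session with responses, for exact-oracle checks."""
    cohort, expected = sa.make_fixture("toy-20-trials", seed=7)
    return cohort, expected


@pytest.fixture(scope="session")
def repulsive_params():
    """Stable, plausibly sized linear-model parameters (short repulsion,
    medium repulsion, weak long attraction; gamma as published)."""
    return LinearParams(
        (LinearComponent(-0.05, 2), LinearComponent(-0.0015, 50),
         LinearComponent(0.0003, 300)),
        (LinearComponent(-0.025, 2), LinearComponent(-0.001, 50),
         LinearComponent(0.0005, 300)),
        gamma=2.56)
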