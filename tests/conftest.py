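import warnings

import numpy as np
import pytest

import priorlik as pl

warnings.filterwarnings("ignore", category=UserWarning)
warnings.filterwarnings("ignore", module="statsmodels")


@pytest.fixture(scope="session")
def plan():
    return pl.generate_session(1)


@pytest.fixture(scope="session")
def avg_plan():
    return pl.generate_averaging_session(2)


@pytest.fixture(scope="session")
def cohort23(plan):
    rng = np.random.default_rng(100)
    participants = pl.draw_participants(23, rng=rng)
    return pl.simulate_cohort(plan, participants, rng)


@pytest.fixture(scope="session")
def ideal_cohort(plan):
    return pl.ideal_observer_cohort(plan)


@pytest.fixture(scope="session")
def small_cohort(plan):
    """8 participants: enough for mixed fits, cheap for cross-checks."""
    rng = np.random.default_rng(7)
    participants = pl.draw_participants(8, rng=rng)
    return pl.simulate_cohort(plan, participants, rng)
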