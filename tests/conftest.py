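import numpy as np
import pytest

from srbsim import (
    ParameterSet,
    RateSchedule,
    ScenarioConfig,
    demo_schedule,
    synthesize_schedule,
)
from srbsim.rates import MAX_AGE, N_FERT_AGES


@pytest.fixture(scope="session")
def demo_sched():
    """Bundled synthetic fertility-transition schedule, 1945-2045."""
    return demo_schedule()


@pytest.fixture(scope="session")
def small_sched():
    """Short declining-fertility schedule for fast engine tests."""
    return synthesize_schedule(1960, 56, tfr_start=2.8, tfr_end=1.2)


@pytest.fixture
def params():
    return ParameterSet()


@pytest.fixture
def fast_config():
    """Desk-scale config for engine tests: small population, short burn-in."""
    return ScenarioConfig(
        start_year=1980,
        end_year=2005,
        burnin_years=20,
        population_size=4000,
        n_replicates=3,
        seed=7,
    )


def flat_schedule(
    years=(2000, 2010), fert_rate=0.1, q_female=0.0, q_male=0.0
) -> RateSchedule:
    """Constant-rate schedule for exact-arithmetic engine checks."""
    yrs = np.arange(years[0], years[1] + 1)
    n = yrs.size
    fertility = np.full((n, N_FERT_AGES), fert_rate)
    mortality = np.zeros((n, MAX_AGE + 1, 2))
    mortality[:, :, 0] = q_female
    mortality[:, :, 1] = q_male
    return RateSchedule(years=yrs, fertility=fertility, mortality=mortality)
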