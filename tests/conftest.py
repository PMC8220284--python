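import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from tdmed.scoring import score_cohort
from tdmed.synthetic import SyntheticConfig, generate_cohort
from tdmed.task import TaskConfig

settings.register_profile(
    "ci", derandomize=True, deadline=None, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def task_cfg() -> TaskConfig:
    return TaskConfig()


@pytest.fixture(scope="session")
def small_cohort():
    """A 300-participant cohort without injected QC violations."""
    cfg = SyntheticConfig(n=300, seed=11, catch_fail_rate=0.0, rt_violation_rate=0.0)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_scored(small_cohort) -> pd.DataFrame:
    return score_cohort(small_cohort.participants, small_cohort.trials)


@pytest.fixture(scope="session")
def large_cohort_scored():
    """A 20,000-participant cohort for consistency checks of the fits."""
    cfg = SyntheticConfig(n=20_000, seed=7, a=0.3, b=0.2, c_prime=0.1,
                          catch_fail_rate=0.0, rt_violation_rate=0.0)
    cohort = generate_cohort(cfg)
    return score_cohort(cohort.participants, cohort.trials), cohort.truth


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
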