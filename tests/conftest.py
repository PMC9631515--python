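import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import glucomod as gm

settings.register_profile(
    "suite", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def std_ga():
    return gm.RaLN(A=990.0, RH=0.4, T1=35.0, W1=0.4, T2=100.0, W2=0.6)


@pytest.fixture(scope="session")
def std_gom(std_ga):
    return gm.GomParams(p1=0.02, p2=0.02, sg=5e-4, beta=30.0,
                        gb=90.0, g0=90.0, x0=0.0, ga=std_ga)


@pytest.fixture(scope="session")
def synthetic_day():
    """One reproducible three-meal day with 2 % glucose noise."""
    subject = gm.draw_subject(11, meal_type="STAND", subject_id="S11")
    return gm.make_day(subject, noise_cv=0.02, seed=3)


@pytest.fixture(scope="session")
def gom_fit(synthetic_day):
    return gm.fit_meal(synthetic_day.meals[0], model="gom", seed=0)


@pytest.fixture(scope="session")
def omm_fit(synthetic_day):
    return gm.fit_meal(synthetic_day.meals[0], model="omm", seed=0)


@pytest.fixture(scope="session")
def recovery_report():
    """The 20-subject, 2 %-noise parameter-recovery experiment."""
    return gm.recovery_experiment(n_subjects=20, seed=1)
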