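import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from steroid_ite.cohort import simulate_default_cohort
from steroid_ite.learners import compact_library
from steroid_ite.super_learner import CrossValidationPlan, fit_super_learner

settings.register_profile(
    "suite", derandomize=True, deadline=None, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


@pytest.fixture(scope="session")
def cohort800():
    """Default calibrated cohort, small enough for fast model fits."""
    return simulate_default_cohort(800, seed=11)


@pytest.fixture(scope="session")
def compact_fsl(cohort800):
    """Super Learner (compact 4-learner library) fitted on cohort800."""
    return fit_super_learner(cohort800, library=compact_library(),
                             plan=CrossValidationPlan(seed=2))
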