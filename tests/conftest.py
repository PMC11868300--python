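import numpy as np
import pytest

from bestpest import (
    CohortConfig,
    ProcedureSettings,
    PsychometricModel,
    generate_cohort,
    run_study,
)


@pytest.fixture(scope="session")
def default_settings() -> ProcedureSettings:
    return ProcedureSettings()


@pytest.fixture(scope="session")
def ideal_observer() -> PsychometricModel:
    """Lapse-free observer whose slope matches the estimator's assumption."""
    return PsychometricModel(threshold=0.23, lapse_rate=0.0)


@pytest.fixture(scope="session")
def small_study(default_settings):
    """A 20-pair, 48-trial simulated study shared across I/O and stats tests."""
    cfg = CohortConfig(n_condition_pairs=20, seed=11)
    cohort = generate_cohort(cfg)
    return run_study(cohort, default_settings, seed=11)
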