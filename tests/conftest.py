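"""Shared fixtures: a seeded 12-subject cohort simulated once per session."""
import numpy as np
import pytest

import visuotactile as vt
from visuotactile.io import PipelineConfig

MASTER_SEED = 0


@pytest.fixture(scope="session")
def design():
    return vt.DesignSpec(seed=MASTER_SEED)


@pytest.fixture(scope="session")
def base_observer():
    return vt.ObserverParams()


@pytest.fixture()
def rng():
    return np.random.default_rng(MASTER_SEED)


@pytest.fixture(scope="session")
def cohort_config():
    return PipelineConfig(seed=MASTER_SEED)


@pytest.fixture(scope="session")
def cohort_trials(cohort_config):
    """Full default cohort: 12 subjects x 21 blocks x 10 trials, fusion mode."""
    return vt.generate_experiment(
        cohort_config.design, cohort_config.observers(), cohort_config.seed
    )


@pytest.fixture(scope="session")
def cohort_summary(cohort_trials, cohort_config):
    return vt.summarize(cohort_trials, cohort_config.design.trial_duration_s)
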