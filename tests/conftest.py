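import numpy as np
import pytest

from swilift import StudyConfig, simulate_study
from swilift.objects import make_object_set


@pytest.fixture(scope="session")
def objects():
    return make_object_set()


@pytest.fixture(scope="session")
def object_by_label(objects):
    return {o.label: o for o in objects}


def noise_free_config(n=2, seed=0):
    """Config with every noise source switched off: exact-recovery regime."""
    cfg = StudyConfig(n_participants=n, seed=seed)
    rm = cfg.rating_model
    rm.beta0_sd = rm.betaW_sd = rm.betaV_sd = rm.betaV_condition_sd = 0.0
    rm.residual_sd = 0.0
    km = cfg.kinematic_model
    km.position_noise_sd_mm = 0.0
    km.reach_duration_between_sd_s = 0.0
    km.reach_duration_cond_sd_s = 0.0
    km.reach_duration_trial_sd_s = 0.0
    return cfg


@pytest.fixture(scope="session")
def small_study():
    """One small but complete synthetic study with tracker streams."""
    return simulate_study(StudyConfig(n_participants=4, seed=11), include_streams=True)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
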