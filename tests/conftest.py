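import numpy as np
import pandas as pd
import pytest

from cardiowalk import synthdata as sd
from cardiowalk.session_io import Anthropometrics, PhaseTimes, SessionRecording


@pytest.fixture(scope="session")
def phases() -> PhaseTimes:
    return PhaseTimes()


@pytest.fixture(scope="session")
def anthro() -> Anthropometrics:
    return Anthropometrics(age=62.0, height_m=1.75, weight_kg=84.0, sex="M")


def make_noise_free_params(hr_rest=70.0, hr_plateau=120.0, rise_tau=60.0, recovery_tau=60.0):
    return sd.HRDynamicsParams(
        hr_rest=hr_rest,
        hr_plateau=hr_plateau,
        rise_tau=rise_tau,
        recovery_tau=recovery_tau,
        hrv_sd=0.0,
        ectopic_rate=0.0,
        dropout_rate=0.0,
    )


@pytest.fixture(scope="session")
def noise_free_session(phases, anthro) -> SessionRecording:
    """One fully deterministic session: exponential HR, clean gait signal."""
    params = make_noise_free_params(rise_tau=30.0)
    gait = sd.GaitParams(cadence=1.8, step_amplitude=0.3, noise_sd=0.0)
    return sd.simulate_session(
        patient_id="P001",
        session_index=1,
        hr_params=params,
        gait=gait,
        anthropometrics=anthro,
        six_mwd=420.0,
        seed=42,
    )


@pytest.fixture(scope="session")
def truth_table() -> pd.DataFrame:
    """Default-size cohort ground truth (no signal synthesis)."""
    return sd.simulate_cohort_truth(sd.CohortConfig(rng_seed=4))


@pytest.fixture(scope="session")
def feature_table(truth_table) -> pd.DataFrame:
    """Cohort feature table built from ground truth (signal-free shortcut)."""
    return sd.truth_to_feature_table(truth_table)


@pytest.fixture(scope="session")
def small_cohort():
    """A small cohort with full signal synthesis (6 patients x 5 sessions)."""
    config = sd.CohortConfig(n_patients=6, rng_seed=2)
    recordings, truth = sd.simulate_cohort(config)
    return config, recordings, truth
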