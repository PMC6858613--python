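import numpy as np
import pytest

from glucoforecast.cohort import PatientArchetype, simulate_cohort, simulate_patient
from glucoforecast.forecaster import LSTMConfig
from glucoforecast.preprocess import prepare_patient


@pytest.fixture(scope="session")
def clean_archetype():
    """Fully observed, moderate-noise archetype for deterministic plumbing tests."""
    return PatientArchetype(
        baseline_glucose=140.0,
        ar_coefficient=0.5,
        carb_effect=0.12,
        exercise_effect=-0.03,
        noise_sd=8.0,
        missing_rate_glucose=0.0,
        missing_rate_lifestyle=0.0,
        n_days=180,
    )


@pytest.fixture(scope="session")
def patient(clean_archetype):
    return simulate_patient(clean_archetype, seed=7)


@pytest.fixture(scope="session")
def prepared(patient):
    return prepare_patient(patient)


@pytest.fixture(scope="session")
def small_cohort():
    return simulate_cohort(n_patients=5, n_archetypes=2, seed=11)


@pytest.fixture(scope="session")
def tiny_config():
    """Small, fast LSTM configuration used wherever training is incidental."""
    return LSTMConfig(
        dropout_rate=0.1, n_lstm_units=8, n_dense_units=6, epochs=60, seed=0
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
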