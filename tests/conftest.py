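from dataclasses import replace

import numpy as np
import pytest

from pulseage import cohort


@pytest.fixture(scope="session")
def clean_config() -> cohort.CohortConfig:
    """Generator config with noise, drift and artifacts disabled."""
    return replace(
        cohort.DEFAULT_CONFIG,
        drift_amplitude=0.0,
        noise_sd_fingertip=0.0,
        noise_sd_ring=0.0,
        artifact_rate_per_min=0.0,
        night_duration_s=150.0,
    )


@pytest.fixture(scope="session")
def participant() -> cohort.Participant:
    return cohort.Participant(
        id="T001", age=45.0, sex="female", bmi=24.0, sbp=118.0, dbp=72.0
    )


@pytest.fixture(scope="session")
def morphology() -> cohort.PulseMorphology:
    return cohort.PulseMorphology(
        a1=1.0, mu1=0.2, sigma1=0.05, a2=0.5, mu2=0.6, sigma2=0.1,
        ramp=0.08, mean_ibi_s=1.0, ibi_jitter_sd_s=0.03,
    )


@pytest.fixture(scope="session")
def clean_recording(participant, clean_config) -> cohort.RawRecording:
    return cohort.simulate_recording(
        participant, "fingertip", clean_config, seed=42
    )


def dense_grid_landmarks(m: cohort.PulseMorphology, n: int = 20001):
    """Independent dense-grid oracle for the closed-form mixture.

    Recomputes the mixture from its definition (sum of two Gaussians
    plus the foot/run-off terms) rather than calling the package's
    feature helper.
    """
    x = np.linspace(0.0, 1.0, n)
    w = m.a1 * np.exp(-0.5 * ((x - m.mu1) / m.sigma1) ** 2)
    w = w + m.a2 * np.exp(-0.5 * ((x - m.mu2) / m.sigma2) ** 2)
    w = w + m.ramp * (1.0 - x) * np.clip(x / cohort.FOOT_RISE_FRAC, 0, 1)
    w = w + cohort.MID_FULLNESS * x * (1.0 - x)
    d = np.diff(w)
    peaks = np.where((d[:-1] > 0) & (d[1:] <= 0))[0] + 1
    return x[peaks], w[peaks], float(w.min())
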