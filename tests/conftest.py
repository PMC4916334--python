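import numpy as np
import pytest

import gaitpal as gp


@pytest.fixture(scope="session")
def treadmill():
    """One simulated 4-speed treadmill calibration session."""
    rec, labels, speeds = gp.simulate_treadmill_session(seed=0)
    return rec, labels, speeds


@pytest.fixture(scope="session")
def calibrated(treadmill):
    """(template, likelihood model) from the shared treadmill session."""
    rec, _, speeds = treadmill
    template, model = gp.calibrate_subject(rec, source_speeds=tuple(set(speeds)))
    return template, model


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def sinusoid_recording(freq_hz, amplitude, duration_s, fs=60.0, axis=2,
                       phase=0.0, subject_id="sin"):
    """Recording with a single-axis sinusoid riding on 1 g gravity."""
    t = np.arange(int(round(duration_s * fs))) / fs
    axes = [np.zeros_like(t) for _ in range(3)]
    axes[axis] = amplitude * np.sin(2 * np.pi * freq_hz * t + phase)
    axes[2] = axes[2] + 1.0
    return gp.TriaxialRecording(subject_id, fs, *axes)
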