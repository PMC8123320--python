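import numpy as np
import pytest

from cardioresp import SimulationConfig, make_trial


@pytest.fixture(scope="session")
def default_trial():
    """One default sitting trial with ground truth (seed fixed)."""
    return make_trial(SimulationConfig(seed=7))


@pytest.fixture(scope="session")
def quiet_config():
    """A noise-free, wander-free configuration for exact spectral checks."""
    return SimulationConfig(
        seed=0, rr_wander_sd=0.0, hr_wander_sd=0.0, noise_sd_strain=0.0,
        noise_sd_imu=0.0, drift_amp=0.0, noise_sd_ecg=0.0,
        noise_sd_ref_resp=0.0, motion_artifact_level=0.0, breathing_leak=0.0,
    )


def dft_peak_hz(trace, fs, low_hz, high_hz):
    """Brute-force oracle: argmax of the full-record DFT magnitude in a band."""
    trace = np.asarray(trace, dtype=float)
    spectrum = np.abs(np.fft.rfft(trace))
    freqs = np.fft.rfftfreq(trace.size, d=1.0 / fs)
    mask = (freqs >= low_hz) & (freqs <= high_hz)
    return float(freqs[mask][np.argmax(spectrum[mask])])


def oracle_find_peaks(trace, height, distance):
    """Exhaustive-scan oracle for peak detection: all strict local maxima
    above ``height``, then greedy minimum-distance pruning keeping the
    tallest peaks first."""
    trace = np.asarray(trace, dtype=float)
    candidates = [i for i in range(1, trace.size - 1)
                  if trace[i] > trace[i - 1] and trace[i] > trace[i + 1]
                  and trace[i] >= height]
    kept: list[int] = []
    for i in sorted(candidates, key=lambda i: trace[i], reverse=True):
        if all(abs(i - j) >= distance for j in kept):
            kept.append(i)
    return np.array(sorted(kept), dtype=int)
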