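"""Heart-rate estimation from IMU-derived beat envelopes.

The accelerometer and gyroscope x-axes carry the heartbeat as an
amplitude-modulated vibration.  After envelope demodulation
(:func:`cardioresp.preprocess.cardiac_envelope`) the dominant spectral peak
inside 0.7-4 Hz gives the heart rate.  Two estimators are provided:

* whole-trial HR: Welch PSD over the full analysis segment;
* windowed HR: one tapered periodogram per 30 s window with 50 % overlap,
  giving an HR trajectory over the trial.

The reference channel is the band-passed ECG analysed through the same
spectral route, so wearable and reference estimates are directly comparable.
No harmonic correction is applied: the estimate is the highest in-band peak,
which can lock onto a harmonic when the fundamental is weak — a known
failure mode, most visible in high-motion (standing) recordings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from . import preprocess
from .respiration import SpectrumEstimate, welch_psd
from .trial_io import TrialRecording, extract_segment

__all__ = [
    "HR_SEARCH_BAND",
    "WindowedHrSeries",
    "hr_from_spectrum",
    "whole_trial_hr",
    "windowed_hr",
]

HR_SEARCH_BAND = (0.7, 4.0)  # Hz

#: Windowed analysis defaults: 30 s Hamming windows, 50 % overlap,
#: zero-padded to a 0.1 beats/min grid.
WINDOW_S = 30.0
WINDOW_OVERLAP = 0.5
WINDOW_GRID_HZ = 0.1 / 60.0

_SOURCES = ("ax", "gx", "ref")


@dataclass
class WindowedHrSeries:
    """Per-window heart rates from the short-time spectral analysis."""

    window_starts: np.ndarray    # s, relative to the analysis segment
    hr_per_window: np.ndarray    # beats/min
    window_length: float = WINDOW_S
    overlap: float = WINDOW_OVERLAP


def hr_from_spectrum(spec: SpectrumEstimate,
                     band: tuple[float, float] = HR_SEARCH_BAND) -> float:
    """Heart rate: 60 x the dominant in-band frequency of an envelope PSD."""
    return 60.0 * spec.band_peak_hz(*band)


def _source_trace(rec: TrialRecording, source: str,
                  envelope_ref: bool = False) -> tuple[np.ndarray, float]:
    """Conditioned cardiac trace for one source on its own clock.

    ``ax``/``gx`` go through the full envelope chain; ``ref`` is the ECG
    band-passed to 0.7-20 Hz (set ``envelope_ref`` to demodulate it through
    the identical envelope chain instead).
    """
    if source not in _SOURCES:
        raise ValueError(f"source must be one of {_SOURCES}")
    if source == "ref":
        fs = rec.fs_ecg
        if envelope_ref:
            return preprocess.cardiac_envelope(rec.ref_ecg, fs), fs
        return preprocess.bandpass_zero_phase(
            rec.ref_ecg, fs, preprocess.CARDIAC_BAND), fs
    fs = rec.fs_ws
    return preprocess.cardiac_envelope(rec.imu_channel(source), fs), fs


def whole_trial_hr(rec: TrialRecording, source: str = "gx",
                   envelope_ref: bool = False,
                   segment_s: float = 60.0) -> float:
    """Average heart rate over the trial's analysis segment, beats/min."""
    seg = extract_segment(rec, *rec.analysis_segment)
    trace, fs = _source_trace(seg, source, envelope_ref)
    spec = welch_psd(trace, fs, segment_s=segment_s)
    return hr_from_spectrum(spec)


def windowed_hr(rec: TrialRecording, source: str = "gx",
                envelope_ref: bool = False,
                window_s: float = WINDOW_S,
                overlap: float = WINDOW_OVERLAP) -> WindowedHrSeries:
    """Short-time heart-rate trajectory: one estimate per 30 s window.

    Each window of the conditioned trace is Hamming-tapered and its
    periodogram searched for the dominant 0.7-4 Hz peak.  Windows advance by
    ``window_s * (1 - overlap)``; a 180 s segment yields 11 windows starting
    at 0, 15, ..., 150 s.
    """
    seg = extract_segment(rec, *rec.analysis_segment)
    trace, fs = _source_trace(seg, source, envelope_ref)
    nwin = int(round(window_s * fs))
    if nwin > trace.size:
        raise ValueError(
            f"{window_s} s window exceeds the {trace.size / fs:.1f} s segment")
    hop = int(round(nwin * (1.0 - overlap)))
    nfft = max(nwin, int(np.ceil(fs / WINDOW_GRID_HZ)))
    starts, rates = [], []
    for i0 in range(0, trace.size - nwin + 1, hop):
        freqs, psd = sps.periodogram(
            trace[i0:i0 + nwin], fs=fs, window="hamming", nfft=nfft,
            detrend=False)
        spec = SpectrumEstimate(freqs=freqs, psd=psd,
                                params={"window_s": window_s})
        starts.append(i0 / fs)
        rates.append(hr_from_spectrum(spec))
    return WindowedHrSeries(window_starts=np.asarray(starts),
                            hr_per_window=np.asarray(rates),
                            window_length=window_s, overlap=overlap)
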