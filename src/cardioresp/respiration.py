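"""Respiratory-rate estimation.

Two estimators operate on the fused, band-passed strain signal (and on the
reference respiratory waveform):

* whole-trial frequency-domain RR: the dominant peak of a Welch power
  spectral density inside the 0.1-1.5 Hz respiratory band, in breaths/min;
* breath-by-breath time-domain RR: end-inspiration peaks detected with a
  temporal threshold derived from the average RR and an amplitude threshold
  proportional to the signal RMS; the n-th breath's rate is 60 divided by
  the n-th inter-peak interval.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy import signal as sps

__all__ = [
    "SpectrumEstimate",
    "BreathSeries",
    "RR_SEARCH_BAND",
    "welch_psd",
    "rr_from_spectrum",
    "detect_breath_peaks",
    "breath_series",
]

RR_SEARCH_BAND = (0.1, 1.5)  # Hz

#: Welch defaults for the ~3 min analysis segment: 60 s Hamming segments with
#: 50 % overlap, zero-padded to a 0.005 Hz grid (0.3 breaths- or beats/min)
#: so sub-unit rate errors are representable.
DEFAULT_WELCH = {"segment_s": 60.0, "window": "hamming",
                 "overlap": 0.5, "grid_hz": 0.005}

#: Amplitude thresholds (fraction of signal RMS) for peak detection: the
#: wearable strain average uses 0.50, the reference waveform 0.40.
AMP_FRACTION_WS = 0.50
AMP_FRACTION_REF = 0.40


@dataclass
class SpectrumEstimate:
    """One-sided PSD on a uniform frequency grid starting at 0 Hz."""

    freqs: np.ndarray       # Hz
    psd: np.ndarray         # power / Hz
    params: Mapping[str, object]

    def band_peak_hz(self, low_hz: float, high_hz: float) -> float:
        """Frequency of the highest in-band peak; ties break toward the
        lower frequency.  Raises if the grid misses the band or the in-band
        spectrum is identically zero (no dominant peak)."""
        mask = (self.freqs >= low_hz) & (self.freqs <= high_hz)
        if not np.any(mask):
            raise ValueError(
                f"frequency grid does not cover {low_hz}-{high_hz} Hz")
        p = self.psd[mask]
        if np.all(p == 0):
            raise ValueError(
                f"spectrum is identically zero in {low_hz}-{high_hz} Hz; "
                "no dominant peak")
        return float(self.freqs[mask][int(np.argmax(p))])

    @property
    def grid_hz(self) -> float:
        return float(self.freqs[1] - self.freqs[0])


@dataclass
class BreathSeries:
    """Detected end-inspiration peaks and the per-breath rates they imply."""

    peak_times: np.ndarray   # s
    intervals: np.ndarray    # s, intervals[n] = peak_times[n+1]-peak_times[n]
    rates: np.ndarray        # breaths/min, 60/intervals


def welch_psd(trace: np.ndarray, fs: float, segment_s: float = 60.0,
              window: str = "hamming", overlap: float = 0.5,
              grid_hz: float = 0.005) -> SpectrumEstimate:
    """Welch overlapped-segment-averaging PSD estimate.

    ``segment_s`` sets the averaging segment; segments are tapered with
    ``window`` and overlapped by ``overlap``.  The FFT is zero-padded so the
    frequency grid is at most ``grid_hz``; no detrending is applied (the
    band restriction downstream excludes DC anyway).
    """
    trace = np.asarray(trace, dtype=float)
    nperseg = int(round(segment_s * fs))
    if nperseg > trace.size:
        raise ValueError(
            f"Welch segment of {segment_s} s ({nperseg} samples) exceeds the "
            f"trace length ({trace.size} samples)")
    nfft = max(nperseg, int(np.ceil(fs / grid_hz)))
    freqs, psd = sps.welch(
        trace, fs=fs, window=window, nperseg=nperseg,
        noverlap=int(round(nperseg * overlap)), nfft=nfft,
        detrend=False, return_onesided=True,
    )
    params = {"segment_s": segment_s, "window": window,
              "overlap": overlap, "zero_pad_to_hz": grid_hz}
    return SpectrumEstimate(freqs=freqs, psd=psd, params=params)


def rr_from_spectrum(spec: SpectrumEstimate,
                     band: tuple[float, float] = RR_SEARCH_BAND) -> float:
    """Whole-trial respiratory rate: 60 x the in-band dominant frequency."""
    return 60.0 * spec.band_peak_hz(*band)


def detect_breath_peaks(trace: np.ndarray, fs: float, avg_rr: float,
                        amp_fraction: float = AMP_FRACTION_WS,
                        separation_factor: float = 0.7) -> np.ndarray:
    """End-inspiration peak times in a conditioned respiratory trace.

    Local maxima qualify when (i) they exceed ``amp_fraction`` of the trace
    RMS and (ii) they are separated by at least ``separation_factor`` times
    the mean breath period ``60/avg_rr`` (closer peaks are pruned keeping the
    taller one, tallest-first).  ``avg_rr`` normally comes from the
    frequency-domain estimate; the guard factor below 1 tolerates the
    natural breath-to-breath variability of self-paced breathing.
    """
    if avg_rr <= 0:
        raise ValueError("avg_rr must be positive")
    if not 0 < amp_fraction:
        raise ValueError("amp_fraction must be positive")
    trace = np.asarray(trace, dtype=float)
    rms = float(np.sqrt(np.mean(trace ** 2)))
    distance = max(1, int(round(separation_factor * 60.0 / avg_rr * fs)))
    peaks, _ = sps.find_peaks(trace, height=amp_fraction * rms,
                              distance=distance)
    return peaks / fs


def breath_series(peak_times: np.ndarray) -> BreathSeries:
    """Per-breath intervals and rates from the detected peak times."""
    peak_times = np.asarray(peak_times, dtype=float)
    if peak_times.size < 2:
        raise ValueError("need at least 2 peaks to form a breath interval")
    intervals = np.diff(peak_times)
    if np.any(intervals <= 0):
        raise ValueError("peak times must be strictly increasing")
    return BreathSeries(peak_times=peak_times, intervals=intervals,
                        rates=60.0 / intervals)


def plausibility_filter(peak_times: np.ndarray,
                        max_rate: float = 90.0) -> np.ndarray:
    """Drop peaks implying an implausible instantaneous rate.

    An automated stand-in for manual inspection of detected peaks: whenever
    two successive peaks imply more than ``max_rate`` breaths/min, the later
    one is discarded.
    """
    peak_times = np.asarray(peak_times, dtype=float)
    if peak_times.size < 2:
        return peak_times
    kept = [peak_times[0]]
    min_gap = 60.0 / max_rate
    for t in peak_times[1:]:
        if t - kept[-1] >= min_gap:
            kept.append(t)
    return np.asarray(kept)
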