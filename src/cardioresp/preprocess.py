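"""Shared signal conditioning: zero-phase band-pass filtering, strain-channel
fusion and Hilbert-envelope demodulation.

Default filter bands follow the monitoring pipeline this package implements:

* respiratory conditioning: 0.05-2 Hz (drops baseline drift, keeps any
  plausible breathing rate);
* cardiac conditioning: 0.7-20 Hz (drops bias and breathing, keeps the
  seismo/gyrocardiographic carrier);
* envelope smoothing: 0.7-5 Hz (isolates the heart-beat envelope after
  demodulation).

All filters are Butterworth designs applied forward-backward (``filtfilt``
style), so the pass-band is the square of the design magnitude and the group
delay is zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

__all__ = [
    "FilterSpec",
    "RESP_BAND",
    "CARDIAC_BAND",
    "ENVELOPE_BAND",
    "bandpass_zero_phase",
    "fuse_strain_channels",
    "hilbert_envelope",
    "cardiac_envelope",
]


@dataclass(frozen=True)
class FilterSpec:
    """Band-pass corner frequencies and design order (before the
    forward-backward application doubles the effective order)."""

    low_hz: float
    high_hz: float
    order: int = 3

    def __post_init__(self) -> None:
        if not 0 <= self.low_hz < self.high_hz:
            raise ValueError("need 0 <= low_hz < high_hz")
        if self.order < 1:
            raise ValueError("order must be >= 1")

    def sos(self, fs: float) -> np.ndarray:
        if self.high_hz >= fs / 2:
            raise ValueError(
                f"high_hz={self.high_hz} Hz is not below the Nyquist "
                f"frequency of a {fs} Hz stream")
        return sps.butter(self.order, [self.low_hz, self.high_hz],
                          btype="bandpass", fs=fs, output="sos")


RESP_BAND = FilterSpec(0.05, 2.0, order=3)
CARDIAC_BAND = FilterSpec(0.7, 20.0, order=3)
ENVELOPE_BAND = FilterSpec(0.7, 5.0, order=3)


def bandpass_zero_phase(trace: np.ndarray, fs: float,
                        spec: FilterSpec) -> np.ndarray:
    """Zero-phase band-pass: the design filter run forward then backward.

    Output has the input's length and no phase distortion; edge transients
    are handled by ``sosfiltfilt``'s default odd-reflection padding.
    """
    trace = np.asarray(trace, dtype=float)
    return sps.sosfiltfilt(spec.sos(fs), trace)


def fuse_strain_channels(channels: np.ndarray) -> np.ndarray:
    """Point-wise arithmetic mean of the four strain-sensor channels."""
    channels = np.asarray(channels, dtype=float)
    if channels.ndim != 2:
        raise ValueError("expected a (n_channels, n_samples) array")
    return channels.mean(axis=0)


def hilbert_envelope(trace: np.ndarray) -> np.ndarray:
    """Amplitude envelope: magnitude of the analytic signal.

    For an amplitude-modulated carrier ``h(t) cos(2 pi f0 t)`` with the
    modulator band-limited below ``f0`` this recovers ``|h(t)|``.
    """
    trace = np.asarray(trace, dtype=float)
    if trace.size < 16:
        raise ValueError("trace too short for a meaningful analytic signal")
    if not np.all(np.isfinite(trace)):
        raise ValueError("non-finite samples")
    return np.abs(sps.hilbert(trace))


def cardiac_envelope(trace: np.ndarray, fs: float,
                     wide: FilterSpec = CARDIAC_BAND,
                     smooth: FilterSpec = ENVELOPE_BAND) -> np.ndarray:
    """Heart-beat envelope of a seismo/gyrocardiographic axis.

    Chain: band-pass 0.7-20 Hz (drop bias, breathing, high-frequency noise)
    -> analytic-signal magnitude -> band-pass 0.7-5 Hz (drop the envelope's
    DC and demodulation ripple).  The result oscillates around zero at the
    beat rate.
    """
    if fs < 50:
        raise ValueError("cardiac envelope extraction expects fs >= 50 Hz")
    x = bandpass_zero_phase(trace, fs, wide)
    h = hilbert_envelope(x)
    return bandpass_zero_phase(h, fs, smooth)
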