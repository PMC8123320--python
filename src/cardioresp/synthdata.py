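"""Synthetic chest-worn-sensor trials with known cardio-respiratory ground truth.

The generator emulates one session of the monitoring protocol: a subject wears
two elastic bands (thoracic and abdominal), each carrying two conductive-textile
strain sensors read out as voltages, plus a 9-axis IMU on the left chest; a
reference device supplies a respiratory waveform at 25 Hz and a single-lead
ECG at 250 Hz.  A trial lasts 200 s: a 10 s breath hold at end-inspiration,
3 min of self-paced breathing, and a final 10 s breath hold.

The physical model:

* Rib-cage strain is quasi-sinusoidal, ``offset + depth*(1 - cos phi)/2`` with
  ``dphi/dt = 2*pi*rr(t)/60`` and a slowly wandering respiratory rate
  ``rr(t)``.  During apnea the strain is held at its end-inspiration value.
* Strain maps to channel voltage through the bench calibration of the textile
  sensors, a second-order polynomial ``y = 0.12 x^2 - 3.81 x + 59.97`` valid
  for strains of 0-10 %, plus white noise and a sub-0.05 Hz sinusoidal drift.
* The heartbeat reaches the IMU as an amplitude-modulated carrier
  ``s(t) = h(t) cos(2*pi*f0*t) + eps(t)``: the beat envelope ``h(t)`` is a
  train of smooth Gaussian bumps at the beat instants, the carrier ``f0``
  sits inside the 0.7-20 Hz seismo/gyrocardiography band.  The accelerometer
  x-axis additionally carries scenario-dependent low-frequency motion
  artifact (standing > sitting > supine); the gyroscope x-axis is cleaner.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import signal as sps

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "CALIBRATION_COEFFS",
    "calibration_polynomial",
    "simulate_breathing_strain",
    "strain_to_voltage",
    "simulate_cardiac_imu",
    "simulate_reference",
    "make_trial",
]

#: Bench calibration of the conductive-textile sensors: voltage-like output
#: as a function of applied strain in percent, valid on [0, 10] %.
CALIBRATION_COEFFS = (0.12, -3.81, 59.97)

#: Default scenario-dependent motion-artifact scale (fraction of cardiac RMS).
#: Standing subjects move most, supine subjects least.
MOTION_ARTIFACT_LEVELS = {"supine": 0.1, "sitting": 0.4, "standing": 1.5}

SCENARIOS = ("sitting", "standing", "supine")

RR_BAND = (0.1, 1.5)  # Hz, respiratory search band
HR_BAND = (0.7, 4.0)  # Hz, cardiac search band
CARRIER_BAND = (0.7, 20.0)  # Hz, band the IMU conditioning preserves


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic trial.

    All rates are physiological (breaths/min, beats/min); sampling rates are
    in Hz.  ``seed`` fully determines every random draw: two trials built from
    equal configs are bit-identical.
    """

    duration_s: float = 200.0
    apnea_s: float = 10.0           # breath-hold length at each end
    fs_ws: float = 100.0            # wearable system (strain + IMU)
    fs_ref_resp: float = 25.0       # reference respiratory waveform
    fs_ecg: float = 250.0           # reference single-lead ECG

    mean_rr: float = 15.0           # breaths/min
    rr_wander_sd: float = 0.5       # breaths/min, slow drift of the rate
    mean_hr: float = 72.0           # beats/min
    hr_wander_sd: float = 1.0       # beats/min

    carrier_freq: float = 10.0      # Hz, heartbeat carrier f0

    scenario: str = "sitting"
    motion_artifact_level: float | None = None  # None -> scenario default

    # breathing mechanics (% strain)
    strain_offset: float = 2.0
    strain_depth: float = 5.0
    abdominal_depth_ratio: float = 0.8
    abdominal_phase_lag: float = 0.3  # rad, abdomen trails the thorax

    # sensor imperfections
    noise_sd_strain: float = 0.3    # voltage units
    drift_amp: float = 1.0          # voltage units
    drift_freq: float = 0.01        # Hz, must stay below 0.05 Hz
    noise_sd_imu: float = 0.3       # fraction of (unit) cardiac RMS
    breathing_leak: float = 0.1     # breathing coupling into IMU, x cardiac RMS
    noise_sd_ecg: float = 0.05
    noise_sd_ref_resp: float = 0.05 # % strain units

    beat_bump_width_s: float = 0.05  # Gaussian sigma of one beat bump
    ecg_pulse_width_s: float = 0.06  # Gaussian sigma of the QRS energy pulse

    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("duration_s", "fs_ws", "fs_ref_resp", "fs_ecg"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.scenario not in SCENARIOS:
            raise ValueError(
                f"scenario must be one of {SCENARIOS}, got {self.scenario!r}"
            )
        if not RR_BAND[0] <= self.mean_rr / 60.0 <= RR_BAND[1]:
            raise ValueError(
                f"mean_rr={self.mean_rr} bpm lies outside the "
                f"{RR_BAND[0]}-{RR_BAND[1]} Hz respiratory search band"
            )
        if not HR_BAND[0] <= self.mean_hr / 60.0 <= HR_BAND[1]:
            raise ValueError(
                f"mean_hr={self.mean_hr} bpm lies outside the "
                f"{HR_BAND[0]}-{HR_BAND[1]} Hz cardiac search band"
            )
        if not CARRIER_BAND[0] < self.carrier_freq < CARRIER_BAND[1]:
            raise ValueError(
                f"carrier_freq={self.carrier_freq} Hz would be destroyed by "
                f"the {CARRIER_BAND[0]}-{CARRIER_BAND[1]} Hz cardiac band-pass"
            )
        if not 0 < self.drift_freq < 0.05:
            raise ValueError("drift_freq must lie in (0, 0.05) Hz so the "
                             "drift is removable by the respiratory filter")
        if self.strain_offset + self.strain_depth > 10.0 or self.strain_offset < 0:
            raise ValueError(
                "strain_offset + strain_depth must stay within the 0-10 % "
                "calibration domain of the textile sensors"
            )
        if 2 * self.apnea_s >= self.duration_s:
            raise ValueError("apnea periods leave no breathing segment")

    @property
    def artifact_level(self) -> float:
        if self.motion_artifact_level is not None:
            return self.motion_artifact_level
        return MOTION_ARTIFACT_LEVELS[self.scenario]

    @property
    def apnea_intervals(self) -> list[tuple[float, float]]:
        return [(0.0, self.apnea_s),
                (self.duration_s - self.apnea_s, self.duration_s)]

    @property
    def n_ws(self) -> int:
        return int(round(self.duration_s * self.fs_ws))

    def rng(self, stream: int) -> np.random.Generator:
        """Independent deterministic substream for one generator stage."""
        return np.random.default_rng([int(self.seed) % 2**31, stream])


@dataclass
class GroundTruth:
    """Simulation bookkeeping: the truth each estimator is compared against."""

    breath_peak_times: np.ndarray   # s, end-inspiration instants
    beat_times: np.ndarray          # s
    rr_profile: np.ndarray          # breaths/min on the wearable clock
    hr_profile: np.ndarray          # beats/min on the wearable clock
    apnea_intervals: list[tuple[float, float]] = field(default_factory=list)
    fs: float = 100.0               # Hz, clock of the rate profiles

    def _segment_mean(self, profile: np.ndarray, start_s: float,
                      end_s: float) -> float:
        t = np.arange(len(profile)) / self.fs
        mask = (t >= start_s) & (t <= end_s)
        return float(np.mean(profile[mask]))

    def mean_rr(self, start_s: float, end_s: float) -> float:
        """Mean instantaneous respiratory rate over [start_s, end_s]."""
        return self._segment_mean(self.rr_profile, start_s, end_s)

    def mean_hr(self, start_s: float, end_s: float) -> float:
        """Mean instantaneous heart rate over [start_s, end_s]."""
        return self._segment_mean(self.hr_profile, start_s, end_s)


def _ou_profile(mean: float, sd: float, n: int, fs: float,
                rng: np.random.Generator, tau_s: float = 30.0,
                clip: tuple[float, float] | None = None) -> np.ndarray:
    """Slowly wandering rate: Ornstein-Uhlenbeck walk around ``mean``.

    ``tau_s`` sets the correlation time; the stationary standard deviation is
    ``sd``.  Values are clipped to ``clip`` to keep rates physiological.
    """
    x = np.zeros(n)
    if sd > 0 and n > 1:
        a = np.exp(-1.0 / (fs * tau_s))
        innov_sd = sd * np.sqrt(1.0 - a * a)
        eps = rng.normal(0.0, innov_sd, n)
        x[0] = rng.normal(0.0, sd)
        for k in range(1, n):
            x[k] = a * x[k - 1] + eps[k]
    out = mean + x
    if clip is not None:
        out = np.clip(out, *clip)
    return out


def calibration_polynomial(strain: np.ndarray | float) -> np.ndarray | float:
    """Noise-free sensor response ``y = 0.12 x^2 - 3.81 x + 59.97``.

    ``strain`` is in percent; the bench calibration covers 0-10 %.
    """
    a, b, c = CALIBRATION_COEFFS
    return a * np.square(strain) + b * np.asanyarray(strain) + c


def simulate_breathing_strain(
    config: SimulationConfig,
) -> tuple[dict[str, np.ndarray], GroundTruth]:
    """Rib-cage strain traces for both bands plus breathing ground truth.

    Returns ``({"thoracic": strain, "abdominal": strain}, gt)`` with strain in
    percent on the wearable clock.  The breathing phase starts and ends at
    end-inspiration so the apnea holds (strain pinned at ``offset + depth``)
    join the oscillation continuously; the wandering-rate profile is rescaled
    by a factor ~1 so the breathing segment contains a whole number of cycles.
    """
    rng = config.rng(1)
    n = config.n_ws
    t = np.arange(n) / config.fs_ws
    rr = _ou_profile(config.mean_rr, config.rr_wander_sd, n, config.fs_ws, rng,
                     clip=(60 * RR_BAND[0], 60 * RR_BAND[1]))

    t0, t1 = config.apnea_s, config.duration_s - config.apnea_s
    breathing = (t >= t0) & (t < t1)
    # integrate the rate only while breathing; force an integer cycle count
    cycles = np.sum(rr[breathing]) / config.fs_ws / 60.0
    n_breaths = max(1, int(round(cycles)))
    rr_scaled = rr * (n_breaths / cycles)

    dphi = np.where(breathing, 2 * np.pi * rr_scaled / 60.0 / config.fs_ws, 0.0)
    phi = np.pi + np.concatenate(([0.0], np.cumsum(dphi)[:-1]))
    strain_th = config.strain_offset + config.strain_depth * (1 - np.cos(phi)) / 2
    # apnea: hold at the end-inspiration value
    strain_th[~breathing] = config.strain_offset + config.strain_depth

    depth_ab = config.strain_depth * config.abdominal_depth_ratio
    phi_ab = np.where(breathing, phi - config.abdominal_phase_lag, np.pi)
    strain_ab = config.strain_offset + depth_ab * (1 - np.cos(phi_ab)) / 2
    strain_ab[~breathing] = config.strain_offset + depth_ab

    # breath peaks: phi crosses pi + 2*pi*k, k = 0..n_breaths-1.  The k = 0
    # peak sits exactly at the end of the leading apnea (the hold is at
    # end-inspiration, so the boundary is a genuine inspiratory peak); the
    # k = n_breaths crossing is the onset of the trailing apnea and belongs
    # to the hold, not to a breathing act.
    # Interpolate only on the strictly increasing (breathing) part of phi and
    # close it with the apnea boundary, so rounding in the cumulative sum
    # cannot push a peak into an apnea plateau.
    targets = np.pi + 2 * np.pi * np.arange(0, n_breaths)
    idx = np.flatnonzero(breathing)
    phi_b = np.append(phi[idx], phi[idx[-1]] + dphi[idx[-1]])
    t_b = np.append(t[idx], t1)
    peak_times = np.interp(targets, phi_b, t_b)

    gt = GroundTruth(
        breath_peak_times=peak_times,
        beat_times=np.empty(0),
        rr_profile=rr_scaled,
        hr_profile=np.empty(0),
        apnea_intervals=config.apnea_intervals,
        fs=config.fs_ws,
    )
    return {"thoracic": strain_th, "abdominal": strain_ab}, gt


def strain_to_voltage(
    strain: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """One sensor channel: calibration polynomial + noise + baseline drift.

    Raises ``ValueError`` for strain outside the 0-10 % calibration domain
    (the polynomial is not validated beyond it).
    """
    strain = np.asarray(strain, dtype=float)
    if strain.min() < 0.0 or strain.max() > 10.0:
        raise ValueError(
            "strain outside the 0-10 % calibration domain; the bench "
            "calibration polynomial cannot be extrapolated"
        )
    if rng is None:
        rng = config.rng(2)
    t = np.arange(strain.size) / config.fs_ws
    y = calibration_polynomial(strain)
    y = y + config.drift_amp * np.sin(
        2 * np.pi * config.drift_freq * t + rng.uniform(0, 2 * np.pi))
    y = y + rng.normal(0.0, config.noise_sd_strain, strain.size)
    return y


def _beat_times(config: SimulationConfig,
                rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Beat instants from a wandering heart-rate profile (integer crossings
    of the accumulated beat phase)."""
    n = config.n_ws
    t = np.arange(n) / config.fs_ws
    hr = _ou_profile(config.mean_hr, config.hr_wander_sd, n, config.fs_ws, rng,
                     clip=(60 * HR_BAND[0], 60 * HR_BAND[1]))
    beat_phase = np.concatenate(([0.0], np.cumsum(hr / 60.0 / config.fs_ws)[:-1]))
    n_beats = int(np.floor(beat_phase[-1]))
    beats = np.interp(np.arange(1, n_beats + 1), beat_phase, t)
    return beats, hr


def _gaussian_bump_train(times: np.ndarray, n: int, fs: float,
                         sigma_s: float) -> np.ndarray:
    """Sum of unit-area Gaussian bumps centred at ``times`` on an n-sample
    grid; evaluated on a +/-5 sigma support for speed."""
    out = np.zeros(n)
    half = int(np.ceil(5 * sigma_s * fs))
    norm = 1.0 / (sigma_s * np.sqrt(2 * np.pi))
    for tc in times:
        c = int(round(tc * fs))
        lo, hi = max(0, c - half), min(n, c + half + 1)
        if lo >= hi:
            continue
        tk = np.arange(lo, hi) / fs
        out[lo:hi] += norm * np.exp(-0.5 * ((tk - tc) / sigma_s) ** 2)
    return out


def _colored_noise(n: int, fs: float, rng: np.random.Generator,
                   cutoff_hz: float = 3.0) -> np.ndarray:
    """Unit-RMS low-frequency noise (body-sway-like motion artifact)."""
    w = rng.normal(0.0, 1.0, n)
    sos = sps.butter(2, cutoff_hz, btype="low", fs=fs, output="sos")
    x = sps.sosfilt(sos, w)
    rms = np.sqrt(np.mean(x ** 2))
    return x / rms if rms > 0 else x


def simulate_cardiac_imu(
    config: SimulationConfig,
    beat_times: np.ndarray,
    breathing_strain: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Accelerometer/gyroscope traces carrying the modulated heartbeat.

    Returns ``(s_ax, s_gx, imu)`` where ``imu`` is the full 9-channel block
    (ax, ay, az, gx, gy, gz, mx, my, mz); rows 0 and 3 are ``s_ax``/``s_gx``,
    the remaining rows are plain noise kept only for format fidelity.

    Both informative axes follow ``s(t) = h(t) cos(2 pi f0 t) + eps(t)`` with
    ``h(t)`` a Gaussian bump train at the beat instants normalised to unit
    RMS.  ``s_ax`` additionally carries low-frequency motion artifact scaled
    by the scenario level; both may carry a small breathing leakage.
    """
    beat_times = np.asarray(beat_times, dtype=float)
    if beat_times.size and (beat_times.min() < 0 or
                            beat_times.max() > config.duration_s):
        raise ValueError("beat_times must lie within [0, duration_s]")
    if rng is None:
        rng = config.rng(3)
    n = config.n_ws
    t = np.arange(n) / config.fs_ws

    h_true = _gaussian_bump_train(beat_times, n, config.fs_ws,
                                  config.beat_bump_width_s)
    cardiac = h_true * np.cos(2 * np.pi * config.carrier_freq * t)
    rms = np.sqrt(np.mean(cardiac ** 2))
    if rms > 0:
        cardiac = cardiac / rms  # unit cardiac RMS: noise scales are relative

    leak = np.zeros(n)
    if breathing_strain is not None and config.breathing_leak > 0:
        b = np.asarray(breathing_strain, dtype=float)
        b = b - b.mean()
        brms = np.sqrt(np.mean(b ** 2))
        if brms > 0:
            leak = config.breathing_leak * b / brms

    s_gx = cardiac + leak + rng.normal(0.0, config.noise_sd_imu, n)
    artifact = config.artifact_level * _colored_noise(n, config.fs_ws, rng)
    s_ax = cardiac + leak + artifact + rng.normal(0.0, config.noise_sd_imu, n)

    imu = rng.normal(0.0, config.noise_sd_imu, (9, n))
    imu[0] = s_ax
    imu[3] = s_gx
    return s_ax, s_gx, imu


def simulate_reference(
    config: SimulationConfig,
    beat_times: np.ndarray,
    breathing_strain: np.ndarray,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Reference-device outputs: ECG-like trace and respiratory waveform.

    The ECG is a train of narrow Gaussian pulses (QRS-duration width, unit
    amplitude) at the beat instants plus white noise, sampled at ``fs_ecg``
    — only R-peak timing is modelled, not electrocardiographic morphology.
    The respiratory waveform is the thoracic strain resampled to
    ``fs_ref_resp`` with independent noise.
    """
    if rng is None:
        rng = config.rng(4)
    n_ecg = int(round(config.duration_s * config.fs_ecg))
    t_ecg = np.arange(n_ecg) / config.fs_ecg
    ecg = np.zeros(n_ecg)
    sigma = config.ecg_pulse_width_s
    half = int(np.ceil(5 * sigma * config.fs_ecg))
    for tc in np.asarray(beat_times, dtype=float):
        c = int(round(tc * config.fs_ecg))
        lo, hi = max(0, c - half), min(n_ecg, c + half + 1)
        if lo >= hi:
            continue
        u = (t_ecg[lo:hi] - tc) / sigma
        ecg[lo:hi] += np.exp(-0.5 * u ** 2)
    ecg += rng.normal(0.0, config.noise_sd_ecg, n_ecg)

    up = int(round(config.fs_ref_resp))
    down = int(round(config.fs_ws))
    resp = sps.resample_poly(np.asarray(breathing_strain, dtype=float), up, down)
    n_resp = int(round(config.duration_s * config.fs_ref_resp))
    resp = resp[:n_resp]
    resp = resp + rng.normal(0.0, config.noise_sd_ref_resp, resp.size)
    return ecg, resp


def make_trial(config: SimulationConfig):
    """Build one complete synthetic trial.

    Returns ``(TrialRecording, GroundTruth)``; the recording carries four
    strain-channel voltages and nine IMU channels at ``fs_ws``, the reference
    respiratory waveform at ``fs_ref_resp`` and the ECG at ``fs_ecg``, with
    the central breathing segment marked as the analysis segment.
    """
    from .trial_io import TrialRecording  # local import to avoid a cycle

    strains, gt = simulate_breathing_strain(config)
    rng_ch = config.rng(2)
    channels = []
    for band in ("thoracic", "thoracic", "abdominal", "abdominal"):
        channels.append(strain_to_voltage(strains[band], config, rng_ch))
    strain_v = np.vstack(channels)

    beats, hr = _beat_times(config, config.rng(5))
    gt.beat_times = beats
    gt.hr_profile = hr

    _, _, imu = simulate_cardiac_imu(config, beats, strains["thoracic"])
    ecg, resp = simulate_reference(config, beats, strains["thoracic"])

    rec = TrialRecording(
        scenario=config.scenario,
        strain=strain_v,
        imu=imu,
        ref_resp=resp,
        ref_ecg=ecg,
        fs_ws=config.fs_ws,
        fs_ref_resp=config.fs_ref_resp,
        fs_ecg=config.fs_ecg,
        analysis_segment=(config.apnea_s, config.duration_s - config.apnea_s),
        meta={"seed": config.seed},
    )
    return rec, gt


def cohort_configs(
    n_subjects: int,
    scenarios: Sequence[str] = SCENARIOS,
    seed: int = 0,
    base: SimulationConfig | None = None,
) -> list[SimulationConfig]:
    """Configs for a cohort: per-subject rates drawn around the defaults,
    one trial per subject x scenario, all derived from one master seed."""
    if base is None:
        base = SimulationConfig()
    rng = np.random.default_rng([int(seed) % 2**31, 99])
    configs = []
    for i in range(n_subjects):
        # resting rates of a healthy young-adult cohort
        mean_rr = float(np.clip(rng.normal(base.mean_rr, 2.0), 8.0, 25.0))
        mean_hr = float(np.clip(rng.normal(base.mean_hr, 6.0), 58.0, 100.0))
        for j, scen in enumerate(scenarios):
            configs.append(replace(
                base, scenario=scen, mean_rr=mean_rr, mean_hr=mean_hr,
                seed=(seed * 1000 + i * 10 + j) % 2**31,
            ))
    return configs
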