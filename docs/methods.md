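# Methods notes

This note records the models, parameter choices and numerical conventions
behind `cardioresp`, including the decisions that were genuinely open.

## Signal models

### Breathing strain

Rib-cage strain is modeled as a raised-cosine oscillation

    strain(t) = offset + depth * (1 - cos phi(t)) / 2,
    dphi/dt   = 2*pi * rr(t) / 60,

with the instantaneous rate `rr(t)` (breaths/min) an Ornstein–Uhlenbeck
walk around `mean_rr` (correlation time 30 s, stationary SD
`rr_wander_sd`), clipped to the 6–30 breaths/min band.  The protocol is a
200 s trial: 10 s breath hold at end-inspiration, 180 s of self-paced
breathing, 10 s breath hold.  During holds the strain is pinned at
`offset + depth` (end-inspiration).  The rate profile is rescaled by a
factor ≈1 so the breathing segment contains a whole number of cycles; the
oscillation therefore starts and ends at end-inspiration and joins both
holds continuously.  Ground-truth breath peaks are the cycle maxima
k = 0..n−1: the k = 0 peak sits exactly at the end of the leading hold
(the hold *is* an inspiration plateau), while the crossing at the onset of
the trailing hold is counted as part of that hold, not as a breathing act.
Two bands share `rr(t)`; the abdominal band has 0.8× the thoracic depth
and trails it by 0.3 rad.

Defaults: offset 2%, depth 5% strain — comfortably inside the 0–10%
calibration domain; `mean_rr` 15 breaths/min, `rr_wander_sd` 0.5
breaths/min, typical of relaxed self-paced breathing.

### Sensor calibration

Channel voltage follows the bench calibration of the conductive textiles,
y = 0.12·x² − 3.81·x + 59.97 for strain x in percent, valid on [0, 10]%
and strictly decreasing there (dy/dx = 0.24x − 3.81 < 0).  Strain outside
the calibrated range is a hard error — the polynomial is not extrapolated.
Each of the four channels adds independent white noise (SD 0.3 voltage
units against a breathing swing of ~14 units) and a sinusoidal baseline
drift (amplitude 1 unit) at 0.01 Hz, deliberately below the 0.05 Hz
high-pass corner of the respiratory filter so drift is removable by
design.  Because the calibration is decreasing, the analysis negates the
fused voltage before peak detection so that end-inspiration appears as a
local maximum.

### Cardiac IMU channels

Both informative axes follow the amplitude-modulation model
s(t) = h(t)·cos(2π·f₀·t) + ε(t).  The beat envelope h(t) is a train of
unit-area Gaussian bumps (σ = 50 ms) at the beat instants, normalized to
unit RMS after modulation so that all noise scales read as fractions of
the cardiac signal.  Beat instants are integer crossings of the integrated
instantaneous heart rate, itself an OU walk (SD `hr_wander_sd` = 1
beat/min, correlation 30 s) around `mean_hr` = 72.  The carrier default
f₀ = 10 Hz sits inside the 0.7–20 Hz SCG band and well above the 5 Hz
envelope cut-off, guaranteeing clean demodulation; carriers outside
(0.7, 20) Hz are rejected at configuration time.

The accelerometer x-axis additionally carries low-frequency motion
artifact: low-pass-filtered (2nd-order, 3 Hz) unit-RMS noise scaled by a
scenario level — supine 0.1, sitting 0.4, standing 1.5 × cardiac RMS —
encoding that standing subjects move most.  The gyroscope x-axis carries
no artifact term, only sensor noise (SD 0.3) and a small breathing
leakage (0.1 × cardiac RMS on both axes), reflecting the accelerometer's
greater sensitivity to whole-body motion.  The remaining seven IMU
channels are plain noise, present only for format fidelity.

The 1 beat/min wander SD is deliberately modest: a spectral-peak estimator
reads the *mode* of the realized rate distribution, so slow wander opens a
gap between the estimate and the time-mean rate of about one SD.  Resting
sessions of the kind emulated here show sub-bpm agreement between
envelope-derived and ECG-derived rates, which constrains the slow drift to
roughly this size.

### Reference channels

The ECG is a train of unit-amplitude Gaussian pulses (σ = 60 ms, the
QRS-energy scale) at the beat instants plus white noise (SD 0.05) at
250 Hz.  Only R-peak timing is modeled — no P/T morphology.  The pulse
width matters spectrally: it sets the decay of the harmonic comb of the
band-passed ECG, and with σ = 60 ms the fundamental dominates the 0.7–4 Hz
search band for rates above ~58 beats/min.  Below that the 0.7 Hz
high-pass attenuates the fundamental enough that the estimator can lock
onto the second harmonic — a real failure mode of spectral HR readers at
low rates, which the synthetic cohort avoids by drawing resting rates in
58–100 beats/min (healthy young adults at rest).  The reference
respiratory waveform is the thoracic strain resampled to 25 Hz with
independent noise.

### What the generator does not emulate

Real recordings add sensor nonlinearity and hysteresis, posture-dependent
pre-strain loss (the published supine outlier), band–support interaction
when lying down, clock drift between wearable and reference, ECG
morphology and ectopy, and broadband motion transients.  Passing recovery
tests on synthetic cohorts therefore demonstrates correctness of the
pipeline under the stated model, not field performance.

## Analysis choices

* **Filters.**  All band-passes are 3rd-order Butterworth designs applied
  forward–backward (`sosfiltfilt`), reproducing the zero-phase route the
  field uses; the effective magnitude response is the square of the design
  response.  Bands: 0.05–2 Hz (respiratory), 0.7–20 Hz (cardiac),
  0.7–5 Hz (envelope smoothing).
* **Envelope definition.**  The heartbeat envelope is the *magnitude* of
  the analytic signal, √(real² + imag²) — the standard demodulation
  definition, chosen over the squared magnitude.
* **Welch parameters** for the ~3 min segment are 60 s Hamming segments
  with 50% overlap, zero-padded to a 0.005 Hz grid (0.3 breaths- or
  beats/min) so that sub-unit rate errors are representable.  No
  detrending is applied (matching the common `pwelch` default); band
  restriction excludes DC anyway.  The 30 s windowed HR analysis uses one
  Hamming-tapered periodogram per window (hop 15 s), zero-padded to a
  0.1 beat/min grid.
* **Band peaks.**  Rates are 60× the argmax of the one-sided PSD inside
  the search band (0.1–1.5 Hz respiratory, 0.7–4 Hz cardiac); ties break
  toward the lower frequency; an identically zero in-band spectrum is an
  error, not a silent zero.  No harmonic correction is applied — when the
  fundamental is weak the estimator reports the harmonic, a documented
  failure mode concentrated in high-motion recordings.
* **Peak detection** uses a minimum separation of
  `separation_factor × 60/avg_rr` seconds with `separation_factor = 0.7`.
  A guard factor below 1 is necessary: self-paced breath intervals
  routinely dip below the mean period, and a separation equal to the mean
  period would prune genuine breaths.  Closer peaks are pruned keeping the
  taller one (tallest-first greedy, the behavior of the classical
  `findpeaks` routine).  Setting the factor to 1.0 restores the literal
  mean-period threshold.  Amplitude thresholds are 0.50 (wearable) and
  0.40 (reference) of the trace RMS over the analysis segment.  The manual
  inspection step used in practice to discard non-inspiratory peaks is
  replaced by an optional automated plausibility filter that drops peaks
  implying >90 breaths/min; explicit exclusion lists can be applied by
  callers working with real data.
* **Analysis segment.**  Apneas are excluded; all RR and HR statistics run
  on the central 180 s breathing segment.  Envelope/amplitude assertions
  in the tests avoid the first and last ~5 s of filtered traces, where
  forward–backward filtering leaves edge transients.
* **Breath pairing.**  Wearable and reference peak lists are matched
  greedily by time proximity (closest pair first, each peak used once)
  within half the median reference breath interval; a rate pair forms for
  every reference interval whose bounding peaks are both matched.
  Spurious or missed peaks drop out and are tallied, never interpolated.
* **Bland–Altman** uses differences ref − ws, MOD = mean difference, and
  LOA = MOD ± 1.96·SD with the sample (n−1) standard deviation — the
  standard convention when it is not otherwise specified.
* **Reference HR route.**  The reference rate is read from the PSD of the
  0.7–20 Hz band-passed ECG; running the ECG through the full envelope
  chain instead is available via `envelope_ref=True`.

## Reproducibility and problem sizes

A `SimulationConfig` plus its integer seed fully determines every sample;
independent substreams (`numpy` `default_rng([seed, stream])`) keep the
stages decoupled.  The test suite and the acceptance script use cohorts of
20 trials per scenario (200 s each at 100/25/250 Hz), which exercise every
stage in seconds while leaving the recovery statistics stable to well
under the asserted tolerances.

## Known limitations

* The whole-trial spectral RR/HR is a single dominant-peak readout; bimodal
  breathing or strong harmonics yield the taller mode with no arbitration.
* The windowed HR inherits the 30 s window's native 2 beats/min resolution;
  zero-padding refines the grid, not the underlying resolution.
* Published per-subject benchmark values are inputs for aggregation-level
  checks only; the raw recordings behind them were never released, so
  subject-level numbers cannot be recomputed.
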