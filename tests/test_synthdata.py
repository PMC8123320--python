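"""Generator checks: calibration model, protocol structure, determinism."""

import numpy as np
import pytest

from cardioresp.synthdata import (
    SimulationConfig,
    calibration_polynomial,
    cohort_configs,
    make_trial,
    simulate_breathing_strain,
    simulate_cardiac_imu,
    simulate_reference,
    strain_to_voltage,
    MOTION_ARTIFACT_LEVELS,
)

from conftest import dft_peak_hz


class TestCalibration:
    def test_polynomial_endpoints(self):
        assert calibration_polynomial(0.0) == pytest.approx(59.97)
        assert calibration_polynomial(10.0) == pytest.approx(33.87)

    def test_strictly_decreasing_on_calibration_domain(self):
        x = np.linspace(0, 10, 2001)
        y = calibration_polynomial(x)
        assert np.all(np.diff(y) < 0)

    def test_noiseless_voltage_equals_polynomial(self):
        cfg = SimulationConfig(noise_sd_strain=0.0, drift_amp=0.0)
        strain = np.linspace(0, 10, 500)
        v = strain_to_voltage(strain, cfg)
        np.testing.assert_allclose(v, calibration_polynomial(strain))

    def test_out_of_domain_strain_rejected(self):
        cfg = SimulationConfig()
        with pytest.raises(ValueError, match="calibration domain"):
            strain_to_voltage(np.array([0.0, 11.0]), cfg)
        with pytest.raises(ValueError, match="calibration domain"):
            strain_to_voltage(np.array([-0.1, 5.0]), cfg)


class TestBreathingStrain:
    def test_breath_count_matches_rate_and_duration(self):
        # 15 breaths/min over the 180 s breathing segment -> 45 acts
        cfg = SimulationConfig(mean_rr=15.0, rr_wander_sd=0.0)
        _, gt = simulate_breathing_strain(cfg)
        assert len(gt.breath_peak_times) == 45

    def test_no_peaks_inside_apneas(self):
        _, gt = simulate_breathing_strain(SimulationConfig(seed=3))
        for start, end in gt.apnea_intervals:
            assert not np.any((gt.breath_peak_times > start)
                              & (gt.breath_peak_times < end))

    def test_peak_intervals_recover_mean_rate(self):
        cfg = SimulationConfig(mean_rr=12.0, rr_wander_sd=0.5, seed=11)
        _, gt = simulate_breathing_strain(cfg)
        rates = 60.0 / np.diff(gt.breath_peak_times)
        assert abs(np.mean(rates) - 12.0) < 0.5

    def test_strain_held_at_end_inspiration_during_apnea(self):
        cfg = SimulationConfig(seed=2)
        strains, _ = simulate_breathing_strain(cfg)
        th = strains["thoracic"]
        n_apnea = int(cfg.apnea_s * cfg.fs_ws)
        peak = cfg.strain_offset + cfg.strain_depth
        assert np.all(th[:n_apnea] == pytest.approx(peak))
        assert np.all(th[-n_apnea:] == pytest.approx(peak))
        assert th.min() >= 0 and th.max() <= 10

    def test_excessive_depth_rejected(self):
        with pytest.raises(ValueError, match="0-10"):
            SimulationConfig(strain_offset=4.0, strain_depth=7.0)

    def test_noise_free_spectral_placement(self, quiet_config):
        # dominant in-band frequency equals mean_rr/60 within one DFT bin
        strains, _ = simulate_breathing_strain(quiet_config)
        seg = strains["thoracic"][1000:19000]
        f = dft_peak_hz(seg - seg.mean(), quiet_config.fs_ws, 0.1, 1.5)
        bin_hz = quiet_config.fs_ws / seg.size
        assert abs(f - quiet_config.mean_rr / 60.0) <= bin_hz + 1e-12


class TestCardiacImu:
    def test_carrier_outside_band_rejected(self):
        with pytest.raises(ValueError, match="carrier"):
            SimulationConfig(carrier_freq=25.0)
        with pytest.raises(ValueError, match="carrier"):
            SimulationConfig(carrier_freq=0.5)

    def test_beat_times_outside_duration_rejected(self):
        cfg = SimulationConfig()
        with pytest.raises(ValueError, match="beat_times"):
            simulate_cardiac_imu(cfg, np.array([5.0, 250.0]))

    def test_scenario_artifact_ordering(self):
        assert (MOTION_ARTIFACT_LEVELS["supine"]
                < MOTION_ARTIFACT_LEVELS["sitting"]
                < MOTION_ARTIFACT_LEVELS["standing"])
        ax_rms = {}
        for scen in ("supine", "standing"):
            cfg = SimulationConfig(scenario=scen, seed=5)
            _, gt = make_trial(cfg)
            s_ax, s_gx, _ = simulate_cardiac_imu(cfg, gt.beat_times)
            ax_rms[scen] = np.sqrt(np.mean(s_ax**2))
        assert ax_rms["standing"] > ax_rms["supine"]

    def test_beat_gaps_follow_hr_profile(self, default_trial):
        _, gt = default_trial
        gaps = np.diff(gt.beat_times)
        mids = (gt.beat_times[1:] + gt.beat_times[:-1]) / 2
        idx = np.clip((mids * gt.fs).astype(int), 0, len(gt.hr_profile) - 1)
        expected = 60.0 / gt.hr_profile[idx]
        assert np.all(np.abs(gaps - expected) / expected < 0.05)

    def test_constant_rate_envelope_peaks_at_beat_frequency(self, quiet_config):
        from cardioresp.preprocess import cardiac_envelope
        beats = np.arange(1.0, 199.0, 1.0)  # exactly 60 beats/min
        _, s_gx, _ = simulate_cardiac_imu(quiet_config, beats)
        env = cardiac_envelope(s_gx, quiet_config.fs_ws)[1000:19000]
        f = dft_peak_hz(env, quiet_config.fs_ws, 0.7, 4.0)
        assert f == pytest.approx(1.0, abs=quiet_config.fs_ws / env.size)


class TestReference:
    def test_reference_stream_lengths_and_beat_count(self, default_trial):
        rec, gt = default_trial
        assert rec.ref_resp.size == round(200 * 25)
        assert rec.ref_ecg.size == round(200 * 250)
        from scipy.signal import find_peaks
        peaks, _ = find_peaks(rec.ref_ecg, height=0.5, distance=int(0.3 * 250))
        assert len(peaks) == len(gt.beat_times)

    def test_reference_resp_spectral_peak(self, quiet_config):
        strains, _ = simulate_breathing_strain(quiet_config)
        _, resp = simulate_reference(quiet_config, np.array([1.0]),
                                     strains["thoracic"])
        from cardioresp.preprocess import bandpass_zero_phase, RESP_BAND
        filt = bandpass_zero_phase(resp, quiet_config.fs_ref_resp, RESP_BAND)
        seg = filt[250:4750]
        f = dft_peak_hz(seg, quiet_config.fs_ref_resp, 0.1, 1.5)
        assert f == pytest.approx(quiet_config.mean_rr / 60.0,
                                  abs=quiet_config.fs_ref_resp / seg.size)


class TestTrialAssembly:
    def test_channel_counts_and_rates(self, default_trial):
        rec, _ = default_trial
        assert rec.strain.shape == (4, 20000)
        assert rec.imu.shape == (9, 20000)
        assert (rec.fs_ws, rec.fs_ref_resp, rec.fs_ecg) == (100.0, 25.0, 250.0)

    def test_same_seed_reproduces_everything(self):
        cfg = SimulationConfig(seed=42)
        rec1, gt1 = make_trial(cfg)
        rec2, gt2 = make_trial(cfg)
        np.testing.assert_array_equal(rec1.strain, rec2.strain)
        np.testing.assert_array_equal(rec1.imu, rec2.imu)
        np.testing.assert_array_equal(rec1.ref_ecg, rec2.ref_ecg)
        np.testing.assert_array_equal(gt1.breath_peak_times,
                                      gt2.breath_peak_times)
        np.testing.assert_array_equal(gt1.beat_times, gt2.beat_times)

    def test_different_seeds_differ(self):
        rec1, _ = make_trial(SimulationConfig(seed=1))
        rec2, _ = make_trial(SimulationConfig(seed=2))
        assert not np.array_equal(rec1.strain, rec2.strain)

    def test_cohort_configs_are_valid_and_distinct(self):
        configs = cohort_configs(3, seed=9)
        assert len(configs) == 9
        assert len({c.seed for c in configs}) == 9
        assert {c.scenario for c in configs} == {"sitting", "standing",
                                                 "supine"}
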