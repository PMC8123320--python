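"""Agreement statistics: errors, breath pairing, MAE, Bland-Altman,
per-scenario aggregation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cardioresp import published
from cardioresp.agreement import (
    PairedRateSeries,
    absolute_error,
    aggregate_report,
    bland_altman,
    mae,
    pair_breaths,
    percentage_error,
)
from cardioresp.respiration import breath_series


class TestScalarErrors:
    @pytest.mark.parametrize("ref,ws,expected", [
        (12.0, 12.0, 0.0),
        (15.0, 14.99, 0.01),
        (10.0, 13.5, 3.5),
    ])
    def test_absolute_error(self, ref, ws, expected):
        assert absolute_error(ref, ws) == pytest.approx(expected)
        assert absolute_error(ws, ref) == pytest.approx(expected)  # symmetry

    def test_percentage_error(self):
        assert percentage_error(20.0, 19.0) == pytest.approx(5.0)
        assert percentage_error(7.3, 7.3) == 0.0
        # scale invariance
        assert percentage_error(24.0, 18.0) == percentage_error(12.0, 9.0)

    def test_percentage_error_needs_positive_reference(self):
        with pytest.raises(ValueError):
            percentage_error(0.0, 5.0)


class TestPairing:
    def test_identical_peak_lists_fully_matched(self):
        peaks = np.array([0.0, 4.0, 8.0, 12.0, 16.0])
        pairs = pair_breaths(breath_series(peaks), breath_series(peaks))
        np.testing.assert_allclose(pairs.ref_rates, pairs.ws_rates)
        assert pairs.pairing["n_pairs"] == 4

    def test_uniform_shift_within_tolerance_keeps_all_pairs(self):
        ref = np.array([0.0, 4.0, 8.0, 12.0, 16.0])
        pairs = pair_breaths(breath_series(ref), breath_series(ref + 0.2))
        assert pairs.pairing["n_pairs"] == 4
        np.testing.assert_allclose(pairs.ref_rates, pairs.ws_rates)

    def test_spurious_extra_peak_is_unmatched(self):
        # trace the greedy rule: the mid-interval extra at 6.1 s is farther
        # from every reference peak than the genuine detections
        ref = np.array([0.0, 4.0, 8.0, 12.0, 16.0])
        ws = np.array([0.1, 4.0, 6.1, 8.1, 12.0, 15.9])
        pairs = pair_breaths(breath_series(ref), breath_series(ws))
        assert pairs.pairing["n_matched_peaks"] == 5
        assert pairs.pairing["n_unmatched_ws"] == 1
        assert pairs.pairing["n_pairs"] == 4
        # the wearable intervals skip the spurious peak entirely
        np.testing.assert_allclose(pairs.ws_rates,
                                   60.0 / np.diff([0.1, 4.0, 8.1, 12.0, 15.9]))

    def test_disjoint_series_raise(self):
        ref = np.array([0.0, 4.0, 8.0])
        ws = np.array([100.0, 104.0])
        with pytest.raises(ValueError, match="paired"):
            pair_breaths(breath_series(ref), breath_series(ws))


class TestMae:
    def test_identical_series_give_zero(self):
        p = PairedRateSeries([15.0, 15.0, 15.0], [15.0, 15.0, 15.0])
        assert mae(p) == (0.0, 0.0)

    def test_hand_arithmetic(self):
        p = PairedRateSeries([10.0, 20.0], [11.0, 18.0])
        m, mp = mae(p)
        assert m == pytest.approx(1.5)
        assert mp == pytest.approx(10.0)  # mean of 10% and 10%

    def test_matches_bruteforce_loop(self):
        rng = np.random.default_rng(11)
        ref = rng.uniform(8, 30, 57)
        ws = ref + rng.normal(0, 1, 57)
        p = PairedRateSeries(ref, np.abs(ws))
        m, mp = mae(p)
        m_o = sum(abs(a - b) for a, b in zip(p.ref_rates, p.ws_rates)) / 57
        mp_o = sum(100 * abs(a - b) / a
                   for a, b in zip(p.ref_rates, p.ws_rates)) / 57
        assert m == pytest.approx(m_o)
        assert mp == pytest.approx(mp_o)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.floats(1.0, 60.0), st.floats(1.0, 60.0)),
                    min_size=1, max_size=40))
    def test_mae_bounds(self, pairs_list):
        ref, ws = map(np.array, zip(*pairs_list))
        m, _ = mae(PairedRateSeries(ref, ws))
        assert 0.0 <= m <= np.max(np.abs(ref - ws)) + 1e-12
        if np.allclose(ref, ws):
            assert m == pytest.approx(0.0, abs=1e-12)


class TestBlandAltman:
    def test_identical_series(self):
        p = PairedRateSeries([12.0, 14.0, 16.0], [12.0, 14.0, 16.0])
        ba = bland_altman(p)
        assert ba.mod == 0.0 and ba.loa_upper == 0.0 and ba.loa_lower == 0.0

    def test_constant_offset(self):
        ref = np.array([10.0, 12.0, 14.0])
        ba = bland_altman(PairedRateSeries(ref, ref - 2.0))
        assert ba.mod == pytest.approx(2.0)
        assert ba.sd == pytest.approx(0.0, abs=1e-12)
        assert ba.loa_upper == pytest.approx(2.0)
        assert ba.loa_lower == pytest.approx(2.0)

    def test_hand_computation_with_sample_sd(self):
        ba = bland_altman(PairedRateSeries([10.0, 12.0, 14.0],
                                           [11.0, 11.0, 15.0]))
        np.testing.assert_allclose(ba.differences, [-1.0, 1.0, -1.0])
        assert ba.mod == pytest.approx(-1.0 / 3.0)
        sd = np.std([-1.0, 1.0, -1.0], ddof=1)  # sample convention
        assert ba.sd == pytest.approx(sd)
        assert ba.loa_upper == pytest.approx(-1.0 / 3.0 + 1.96 * sd)
        assert ba.loa_lower == pytest.approx(-1.0 / 3.0 - 1.96 * sd)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.floats(5.0, 40.0), st.floats(5.0, 40.0)),
                    min_size=2, max_size=50))
    def test_loa_identity_holds_by_construction(self, pairs_list):
        ref, ws = map(np.array, zip(*pairs_list))
        ba = bland_altman(PairedRateSeries(ref, ws))
        assert ba.loa_upper - ba.loa_lower == pytest.approx(2 * 1.96 * ba.sd)
        assert (ba.loa_upper + ba.loa_lower) / 2 == pytest.approx(ba.mod)
        np.testing.assert_allclose(ba.means, (ref + ws) / 2)

    def test_single_pair_rejected(self):
        with pytest.raises(ValueError):
            bland_altman(PairedRateSeries([10.0], [11.0]))


class TestAggregation:
    def test_average_row_is_column_mean(self):
        df = pd.DataFrame({"Sitting": [1.0, 2.0, 3.0],
                           "Supine": [2.0, 2.0, 2.0]})
        agg = aggregate_report(df)
        assert agg.loc["Average", "Sitting"] == pytest.approx(2.0)
        assert agg.loc["Average", "Supine"] == pytest.approx(2.0)

    def test_single_subject_average_is_that_subject(self):
        agg = aggregate_report(pd.DataFrame({"Standing": [0.61]}))
        assert agg.loc["Average", "Standing"] == pytest.approx(0.61)

    def test_reproduces_benchmark_rr_sitting_average(self):
        agg = aggregate_report(published.rr_abs_error_bpm())
        assert agg.loc["Average", "Sitting"] == pytest.approx(0.17, abs=0.005)

    def test_reproduces_benchmark_hr_standing_average(self):
        agg = aggregate_report(published.hr_abs_error_bpm("gx"))
        assert agg.loc["Average", "Standing"] == pytest.approx(3.81, abs=0.005)

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            aggregate_report(pd.DataFrame())
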