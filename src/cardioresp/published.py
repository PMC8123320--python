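"""Benchmark agreement tables from the original validation study of the
chest-worn strain + IMU monitoring system (8 subjects x 3 postures).

These per-subject error values are inputs to the aggregation routines:
recomputing each table's Average row from its per-subject entries checks
:func:`cardioresp.agreement.aggregate_report` against the published
aggregates, and the published Bland-Altman rows check the
``LOA = MOD +/- 1.96 SD`` identity.  The raw recordings behind these numbers
were never released, so the numbers themselves are not recomputable — only
their internal consistency is.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "SCENARIOS",
    "SUBJECTS",
    "rr_abs_error_bpm",
    "rr_pct_error",
    "rr_mae_bpm",
    "rr_mae_pct",
    "hr_abs_error_bpm",
    "hr_pct_error",
    "hr_windowed_abs_error_bpm",
    "hr_windowed_pct_error",
    "bland_altman_rr",
    "published_averages",
]

SCENARIOS = ["Sitting", "Standing", "Supine"]
SUBJECTS = list(range(1, 9))


def _table(values: list[list[float]]) -> pd.DataFrame:
    return pd.DataFrame(values, index=SUBJECTS, columns=SCENARIOS)


def rr_abs_error_bpm() -> pd.DataFrame:
    """Whole-trial RR absolute error per subject, breaths/min."""
    return _table([
        [0.99, 0.01, 0.01],
        [0.06, 2.39, 0.36],
        [0.07, 0.06, 0.01],
        [0.02, 0.01, 0.03],
        [0.04, 0.00, 0.13],
        [0.01, 0.01, 0.01],
        [0.11, 0.27, 0.34],
        [0.04, 0.01, 22.57],
    ])


def rr_pct_error() -> pd.DataFrame:
    """Whole-trial RR percentage error per subject, %."""
    return _table([
        [6.78, 0.05, 0.87],
        [0.40, 25.43, 2.16],
        [0.95, 0.72, 0.08],
        [0.09, 0.10, 0.13],
        [0.33, 0.01, 1.19],
        [0.06, 0.08, 0.04],
        [0.72, 1.47, 2.58],
        [0.32, 0.07, 66.94],
    ])


def rr_mae_bpm() -> pd.DataFrame:
    """Breath-by-breath RR mean absolute error per subject, breaths/min."""
    return _table([
        [0.24, 0.61, 1.16],
        [0.30, 0.28, 1.08],
        [0.22, 0.39, 1.11],
        [0.24, 0.33, 3.14],
        [0.11, 0.11, 1.92],
        [0.18, 0.25, 0.87],
        [0.36, 0.23, 1.78],
        [0.05, 0.23, 0.07],
    ])


def rr_mae_pct() -> pd.DataFrame:
    """Breath-by-breath RR mean absolute percentage error per subject, %."""
    return _table([
        [1.52, 3.17, 7.72],
        [1.44, 2.25, 7.41],
        [2.56, 3.59, 9.08],
        [1.36, 1.89, 15.00],
        [0.91, 0.81, 18.09],
        [1.15, 1.64, 5.65],
        [2.25, 1.29, 12.57],
        [0.37, 1.93, 0.57],
    ])


def hr_abs_error_bpm(source: str = "gx") -> pd.DataFrame:
    """Whole-trial HR absolute error per subject, beats/min.

    ``source`` selects the gyroscope ("gx") or accelerometer ("ax") x-axis
    envelope used for the wearable estimate.
    """
    if source == "gx":
        return _table([
            [0.56, 2.92, 0.89],
            [3.83, 0.05, 0.18],
            [5.19, 5.97, 0.03],
            [0.28, 13.07, 0.09],
            [0.13, 1.98, 0.06],
            [0.30, 0.23, 0.28],
            [0.18, 6.20, 0.02],
            [0.25, 0.08, 0.80],
        ])
    if source == "ax":
        return _table([
            [0.41, 32.80, 0.06],
            [3.83, 0.05, 0.18],
            [8.45, 24.55, 0.03],
            [6.29, 0.73, 2.23],
            [0.13, 0.02, 0.06],
            [3.04, 9.93, 0.28],
            [0.16, 36.21, 0.02],
            [0.25, 6.24, 0.12],
        ])
    raise ValueError("source must be 'gx' or 'ax'")


def hr_pct_error(source: str = "gx") -> pd.DataFrame:
    """Whole-trial HR percentage error per subject, %."""
    if source == "gx":
        return _table([
            [0.83, 6.44, 1.53],
            [5.54, 0.06, 0.28],
            [7.96, 7.37, 0.06],
            [0.41, 17.98, 0.14],
            [0.21, 2.69, 0.10],
            [0.35, 0.23, 0.37],
            [0.31, 11.21, 0.04],
            [0.30, 0.09, 1.14],
        ])
    if source == "ax":
        return _table([
            [0.61, 72.34, 0.11],
            [5.54, 0.06, 0.28],
            [12.96, 30.31, 0.06],
            [9.16, 1.00, 3.59],
            [0.21, 0.03, 0.10],
            [3.53, 9.85, 0.37],
            [0.28, 65.49, 0.04],
            [0.30, 7.01, 0.17],
        ])
    raise ValueError("source must be 'gx' or 'ax'")


def hr_windowed_abs_error_bpm() -> pd.DataFrame:
    """30 s windowed HR absolute error (gyroscope envelope), beats/min."""
    return _table([
        [5.45, 27.27, 0.18],
        [0.00, 27.45, 0.67],
        [13.45, 16.18, 1.00],
        [8.60, 4.60, 5.20],
        [0.20, 0.00, 0.00],
        [0.20, 35.60, 28.73],
        [0.80, 15.20, 0.00],
        [0.20, 0.20, 0.40],
    ])


def hr_windowed_pct_error() -> pd.DataFrame:
    """30 s windowed HR percentage error (gyroscope envelope), %."""
    return _table([
        [8.02, 53.99, 0.29],
        [0.00, 16.99, 1.08],
        [20.96, 20.91, 1.98],
        [13.03, 6.33, 8.01],
        [0.31, 0.00, 0.00],
        [0.23, 30.01, 13.42],
        [1.30, 22.56, 0.00],
        [0.29, 0.24, 0.58],
    ])


def bland_altman_rr() -> pd.DataFrame:
    """Published breath-by-breath Bland-Altman summary per scenario
    (MOD and limits of agreement, breaths/min)."""
    return pd.DataFrame(
        {
            "MOD": [-0.0039, 0.0186, -0.2948],
            "LOA_upper": [0.9391, 1.6753, 4.9264],
            "LOA_lower": [-0.9470, -1.6392, -5.5160],
        },
        index=SCENARIOS,
    )


def published_averages() -> dict[str, dict[str, float]]:
    """The across-subject Average rows as printed in the study's tables."""
    return {
        "rr_abs_error_bpm": {"Sitting": 0.17, "Standing": 0.35, "Supine": 2.95},
        "rr_pct_error": {"Sitting": 1.21, "Standing": 3.49, "Supine": 9.25},
        "rr_mae_bpm": {"Sitting": 0.21, "Standing": 0.30, "Supine": 1.39},
        "rr_mae_pct": {"Sitting": 1.45, "Standing": 2.07, "Supine": 9.51},
        "hr_abs_error_bpm_gx": {"Sitting": 1.34, "Standing": 3.81, "Supine": 0.29},
        "hr_abs_error_bpm_ax": {"Sitting": 2.82, "Standing": 13.82, "Supine": 0.37},
        "hr_pct_error_gx": {"Sitting": 1.99, "Standing": 5.75, "Supine": 0.46},
        "hr_pct_error_ax": {"Sitting": 4.07, "Standing": 23.26, "Supine": 0.59},
        "hr_windowed_abs_error_bpm": {"Sitting": 3.61, "Standing": 15.81, "Supine": 4.52},
        "hr_windowed_pct_error": {"Sitting": 5.52, "Standing": 18.88, "Supine": 3.17},
    }
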