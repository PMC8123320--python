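"""Method-agreement statistics between wearable and reference estimates.

Covers the per-subject absolute and percentage errors of the rate
estimators, breath pairing, breath-by-breath mean absolute error (MAE),
Bland-Altman analysis (mean of differences and limits of agreement) and the
per-scenario aggregation that produces subjects x scenarios error tables
with an Average row.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .respiration import BreathSeries

__all__ = [
    "PairedRateSeries",
    "BlandAltmanResult",
    "AgreementReport",
    "absolute_error",
    "percentage_error",
    "pair_breaths",
    "mae",
    "bland_altman",
    "aggregate_report",
]


@dataclass
class PairedRateSeries:
    """Element-wise paired reference/wearable rates (breaths- or beats/min)."""

    ref_rates: np.ndarray
    ws_rates: np.ndarray
    pairing: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.ref_rates = np.asarray(self.ref_rates, dtype=float)
        self.ws_rates = np.asarray(self.ws_rates, dtype=float)
        if self.ref_rates.shape != self.ws_rates.shape:
            raise ValueError("paired series must have equal length")
        if self.ref_rates.size < 1:
            raise ValueError("need at least one pair")
        both = np.concatenate([self.ref_rates, self.ws_rates])
        if not np.all(np.isfinite(both)) or np.any(both <= 0):
            raise ValueError("rates must be finite and positive")


@dataclass
class BlandAltmanResult:
    """Bland-Altman summary: per-pair means/differences, MOD and LOAs."""

    means: np.ndarray        # (ref + ws) / 2 per pair
    differences: np.ndarray  # ref - ws per pair
    mod: float               # mean of differences
    sd: float                # sample SD of differences (n-1 denominator)
    loa_upper: float         # mod + 1.96 sd
    loa_lower: float         # mod - 1.96 sd


@dataclass
class AgreementReport:
    """Per-estimator error tables (subjects x scenarios + Average row) and
    Bland-Altman summaries keyed by scenario."""

    tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    bland_altman: dict[str, BlandAltmanResult] = field(default_factory=dict)


def absolute_error(ref_value: float, ws_value: float) -> float:
    """|reference - wearable|, in the rate's own units."""
    return float(abs(ref_value - ws_value))


def percentage_error(ref_value: float, ws_value: float) -> float:
    """100 x |reference - wearable| / reference."""
    if ref_value <= 0:
        raise ValueError("percentage error needs a positive reference value")
    return 100.0 * abs(ref_value - ws_value) / ref_value


def pair_breaths(ref: BreathSeries, ws: BreathSeries,
                 tolerance_s: float | None = None) -> PairedRateSeries:
    """Pair wearable breaths with reference breaths via their peaks.

    Peaks are matched greedily by time proximity (closest pairs first, each
    peak used at most once) within ``tolerance_s`` (default: half the median
    reference breath interval).  A rate pair is then formed for every
    reference breath whose two bounding peaks are both matched; its wearable
    rate comes from the interval between the two matched wearable peaks.
    Unmatched/spurious peaks therefore drop out of the comparison and are
    tallied in the pairing record.
    """
    rp = np.asarray(ref.peak_times, dtype=float)
    wp = np.asarray(ws.peak_times, dtype=float)
    if rp.size < 2 or wp.size < 2:
        raise ValueError("both series need at least two peaks")
    if tolerance_s is None:
        tolerance_s = 0.5 * float(np.median(np.diff(rp)))

    # greedy closest-first matching within tolerance
    dt = np.abs(rp[:, None] - wp[None, :])
    order = np.argsort(dt, axis=None, kind="stable")
    match: dict[int, int] = {}
    used_ws: set[int] = set()
    for flat in order:
        i, j = divmod(int(flat), wp.size)
        if dt[i, j] > tolerance_s:
            break
        if i in match or j in used_ws:
            continue
        match[i] = j
        used_ws.add(j)

    ref_rates, ws_rates = [], []
    for i in range(rp.size - 1):
        if i in match and (i + 1) in match:
            w0, w1 = wp[match[i]], wp[match[i + 1]]
            if w1 <= w0:
                continue
            ref_rates.append(60.0 / (rp[i + 1] - rp[i]))
            ws_rates.append(60.0 / (w1 - w0))
    if not ref_rates:
        raise ValueError("no breaths could be paired within tolerance")
    pairing = {
        "n_ref_peaks": int(rp.size),
        "n_ws_peaks": int(wp.size),
        "n_matched_peaks": len(match),
        "n_unmatched_ref": int(rp.size - len(match)),
        "n_unmatched_ws": int(wp.size - len(match)),
        "n_pairs": len(ref_rates),
        "tolerance_s": float(tolerance_s),
    }
    return PairedRateSeries(ref_rates=np.asarray(ref_rates),
                            ws_rates=np.asarray(ws_rates), pairing=pairing)


def mae(pairs: PairedRateSeries) -> tuple[float, float]:
    """Breath-by-breath mean absolute error and its percentage form.

    The percentage form averages the per-breath ratios
    ``|ref - ws| / ref`` (x100), not the ratio of the averages.
    """
    diff = np.abs(pairs.ref_rates - pairs.ws_rates)
    return float(np.mean(diff)), float(100.0 * np.mean(diff / pairs.ref_rates))


def bland_altman(pairs: PairedRateSeries) -> BlandAltmanResult:
    """Bland-Altman agreement between reference and wearable rates.

    Differences use the convention ``ref - ws``; the limits of agreement are
    ``MOD +/- 1.96 x SD`` with the sample (n-1) standard deviation.
    """
    if pairs.ref_rates.size < 2:
        raise ValueError("Bland-Altman needs at least two pairs")
    diff = pairs.ref_rates - pairs.ws_rates
    means = (pairs.ref_rates + pairs.ws_rates) / 2.0
    mod = float(np.mean(diff))
    sd = float(np.std(diff, ddof=1))
    return BlandAltmanResult(
        means=means, differences=diff, mod=mod, sd=sd,
        loa_upper=mod + 1.96 * sd, loa_lower=mod - 1.96 * sd,
    )


def aggregate_report(per_subject: pd.DataFrame | Mapping,
                     average_label: str = "Average") -> pd.DataFrame:
    """Append the across-subject Average row to a subjects x scenarios table.

    ``per_subject`` holds one row per subject and one column per scenario;
    the returned copy carries an extra row with the arithmetic mean of each
    column.
    """
    df = pd.DataFrame(per_subject).astype(float)
    if df.empty:
        raise ValueError("no per-subject entries to aggregate")
    out = df.copy()
    out.loc[average_label] = df.mean(axis=0)
    return out
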