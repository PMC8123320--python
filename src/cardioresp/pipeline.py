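"""End-to-end analysis: trials in, agreement report out.

Each trial is processed on its analysis segment (the central self-paced
breathing period, apneas excluded):

1. respiratory: fuse the four strain channels, band-pass 0.05-2 Hz, Welch
   PSD -> whole-trial RR; peak detection -> breath-by-breath RR; the same on
   the reference waveform; errors and Bland-Altman pairs vs the reference;
2. cardiac: envelope-demodulate the accelerometer and gyroscope x-axes,
   Welch PSD -> whole-trial HR per source; 30 s windowed HR on the gyroscope
   envelope; errors vs the band-passed reference ECG analysed identically.

Per-scenario aggregation mirrors the subjects x scenarios error tables with
an across-subject Average row.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import agreement, cardiac, preprocess, respiration, synthdata
from .agreement import AgreementReport, PairedRateSeries
from .synthdata import SimulationConfig
from .trial_io import TrialRecording, extract_segment, load_trial

__all__ = ["RunConfig", "TrialResult", "analyze_trial", "run_pipeline"]


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Either ``input_dir`` (a directory of trial subdirectories) or synthetic
    cohort parameters (``n_subjects`` x ``scenarios``).  All detection and
    spectral defaults mirror the monitoring pipeline's stated values.
    """

    input_dir: str | Path | None = None
    n_subjects: int = 8
    scenarios: Sequence[str] = ("sitting", "standing", "supine")
    seed: int = 0
    out_dir: str | Path | None = None
    base_simulation: SimulationConfig | None = None

    amp_fraction_ws: float = respiration.AMP_FRACTION_WS
    amp_fraction_ref: float = respiration.AMP_FRACTION_REF
    separation_factor: float = 0.7
    welch_segment_s: float = 60.0


@dataclass
class TrialResult:
    """Per-trial estimates and errors."""

    trial_id: str
    scenario: str
    metrics: dict[str, float] = field(default_factory=dict)
    pairs: PairedRateSeries | None = None
    error: str | None = None


def analyze_trial(rec: TrialRecording, run: RunConfig | None = None,
                  trial_id: str = "trial") -> TrialResult:
    """Full RR + HR analysis of one recording vs its reference channels."""
    run = run or RunConfig()
    seg = extract_segment(rec, *rec.analysis_segment)
    m: dict[str, float] = {}

    # --- respiratory, frequency domain
    # the textile calibration is strictly decreasing in strain, so negate the
    # fused voltage to make end-inspiration a local maximum
    r_ws = -preprocess.fuse_strain_channels(seg.strain)
    r_ws = preprocess.bandpass_zero_phase(r_ws, seg.fs_ws, preprocess.RESP_BAND)
    r_ref = preprocess.bandpass_zero_phase(seg.ref_resp, seg.fs_ref_resp,
                                           preprocess.RESP_BAND)
    rr_ws = respiration.rr_from_spectrum(
        respiration.welch_psd(r_ws, seg.fs_ws, segment_s=run.welch_segment_s))
    rr_ref = respiration.rr_from_spectrum(
        respiration.welch_psd(r_ref, seg.fs_ref_resp,
                              segment_s=run.welch_segment_s))
    m["rr_ws_bpm"] = rr_ws
    m["rr_ref_bpm"] = rr_ref
    m["rr_abs_error_bpm"] = agreement.absolute_error(rr_ref, rr_ws)
    m["rr_pct_error"] = agreement.percentage_error(rr_ref, rr_ws)

    # --- respiratory, breath by breath
    peaks_ws = respiration.detect_breath_peaks(
        r_ws, seg.fs_ws, avg_rr=rr_ws, amp_fraction=run.amp_fraction_ws,
        separation_factor=run.separation_factor)
    peaks_ref = respiration.detect_breath_peaks(
        r_ref, seg.fs_ref_resp, avg_rr=rr_ref,
        amp_fraction=run.amp_fraction_ref,
        separation_factor=run.separation_factor)
    pairs = agreement.pair_breaths(respiration.breath_series(peaks_ref),
                                   respiration.breath_series(peaks_ws))
    m["rr_mae_bpm"], m["rr_mae_pct"] = agreement.mae(pairs)
    ba = agreement.bland_altman(pairs)
    m["rr_ba_mod_bpm"] = ba.mod
    m["rr_ba_loa_upper_bpm"] = ba.loa_upper
    m["rr_ba_loa_lower_bpm"] = ba.loa_lower

    # --- cardiac, whole trial
    hr_ref = cardiac.whole_trial_hr(rec, source="ref",
                                    segment_s=run.welch_segment_s)
    m["hr_ref_bpm"] = hr_ref
    for source in ("ax", "gx"):
        hr = cardiac.whole_trial_hr(rec, source=source,
                                    segment_s=run.welch_segment_s)
        m[f"hr_{source}_bpm"] = hr
        m[f"hr_{source}_abs_error_bpm"] = agreement.absolute_error(hr_ref, hr)
        m[f"hr_{source}_pct_error"] = agreement.percentage_error(hr_ref, hr)

    # --- cardiac, 30 s windows (gyroscope envelope vs windowed reference)
    win_gx = cardiac.windowed_hr(rec, source="gx")
    win_ref = cardiac.windowed_hr(rec, source="ref")
    n = min(win_gx.hr_per_window.size, win_ref.hr_per_window.size)
    abs_err = np.abs(win_ref.hr_per_window[:n] - win_gx.hr_per_window[:n])
    pct_err = 100.0 * abs_err / win_ref.hr_per_window[:n]
    m["hr_windowed_abs_error_bpm"] = float(np.mean(abs_err))
    m["hr_windowed_pct_error"] = float(np.mean(pct_err))
    m["n_windows"] = float(n)

    return TrialResult(trial_id=trial_id, scenario=rec.scenario,
                       metrics=m, pairs=pairs)


#: metric -> report-table name for the per-scenario aggregation
_TABLE_METRICS = {
    "rr_abs_error_bpm": "rr_abs_error_bpm",
    "rr_pct_error": "rr_pct_error",
    "rr_mae_bpm": "rr_mae_bpm",
    "rr_mae_pct": "rr_mae_pct",
    "hr_gx_abs_error_bpm": "hr_abs_error_bpm_gx",
    "hr_gx_pct_error": "hr_pct_error_gx",
    "hr_ax_abs_error_bpm": "hr_abs_error_bpm_ax",
    "hr_ax_pct_error": "hr_pct_error_ax",
    "hr_windowed_abs_error_bpm": "hr_windowed_abs_error_bpm",
    "hr_windowed_pct_error": "hr_windowed_pct_error",
}


def _aggregate(results: list[TrialResult]) -> AgreementReport:
    ok = [r for r in results if r.error is None]
    report = AgreementReport()
    scenarios = sorted({r.scenario for r in ok})
    for metric, table_name in _TABLE_METRICS.items():
        rows: dict[str, dict[str, float]] = {}
        for r in ok:
            rows.setdefault(r.trial_id.split("/")[0], {})[r.scenario] = \
                r.metrics[metric]
        if not rows:
            continue
        df = pd.DataFrame.from_dict(rows, orient="index")
        df = df.reindex(columns=scenarios)
        report.tables[table_name] = agreement.aggregate_report(df)
    # pooled Bland-Altman per scenario over all subjects' breath pairs
    for scen in scenarios:
        refs = np.concatenate([r.pairs.ref_rates for r in ok
                               if r.scenario == scen and r.pairs is not None])
        wss = np.concatenate([r.pairs.ws_rates for r in ok
                              if r.scenario == scen and r.pairs is not None])
        if refs.size >= 2:
            report.bland_altman[scen] = agreement.bland_altman(
                PairedRateSeries(ref_rates=refs, ws_rates=wss))
    return report


def _iter_trials(run: RunConfig):
    """Yield (trial_id, recording) either from disk or the synthetic cohort."""
    if run.input_dir is not None:
        root = Path(run.input_dir)
        trial_dirs = sorted(p for p in root.iterdir()
                            if p.is_dir() and (p / "meta.txt").exists())
        if not trial_dirs:
            raise FileNotFoundError(f"no trial directories under {root}")
        for p in trial_dirs:
            yield p.name, lambda p=p: load_trial(p)
    else:
        configs = synthdata.cohort_configs(
            run.n_subjects, run.scenarios, seed=run.seed,
            base=run.base_simulation)
        for i, cfg in enumerate(configs):
            subject = i // len(run.scenarios) + 1
            tid = f"S{subject:02d}/{cfg.scenario}"
            yield tid, lambda cfg=cfg: synthdata.make_trial(cfg)[0]


def run_pipeline(run: RunConfig) -> tuple[AgreementReport, list[TrialResult]]:
    """Analyze every trial, aggregate per scenario, optionally write outputs.

    A failing trial is recorded (with its error message) and the run
    continues; ``RuntimeError`` is raised only if every trial fails.
    """
    results: list[TrialResult] = []
    for tid, make in _iter_trials(run):
        try:
            rec = make()
            results.append(analyze_trial(rec, run, trial_id=tid))
        except Exception as exc:  # keep going, report at the end
            results.append(TrialResult(trial_id=tid, scenario="?",
                                       error=str(exc)))
    if all(r.error is not None for r in results):
        raise RuntimeError("all trials failed: "
                           + "; ".join(f"{r.trial_id}: {r.error}"
                                       for r in results))
    report = _aggregate(results)
    if run.out_dir is not None:
        write_report(report, results, run.out_dir)
    return report, results


def write_report(report: AgreementReport, results: list[TrialResult],
                 out_dir: str | Path) -> None:
    """Report bundle: one CSV per error table, Bland-Altman scatter CSVs and
    a JSON summary (deterministic for a fixed input)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, df in report.tables.items():
        df.round(2).to_csv(out / f"{name}.csv")
    for scen, ba in report.bland_altman.items():
        pd.DataFrame({"mean": ba.means, "diff": ba.differences}).to_csv(
            out / f"bland_altman_{scen}.csv", index=False,
            float_format="%.6f")
    summary = {
        "trials": {
            r.trial_id: (
                {k: round(v, 6) for k, v in sorted(r.metrics.items())}
                if r.error is None else {"error": r.error}
            )
            for r in results
        },
        "scenario_averages": {
            name: {c: round(float(df.loc["Average", c]), 6)
                   for c in df.columns}
            for name, df in sorted(report.tables.items())
        },
        "bland_altman": {
            scen: {"MOD": round(ba.mod, 6),
                   "LOA_upper": round(ba.loa_upper, 6),
                   "LOA_lower": round(ba.loa_lower, 6)}
            for scen, ba in sorted(report.bland_altman.items())
        },
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2,
                                                 sort_keys=True) + "\n")
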