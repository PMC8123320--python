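"""Reading, writing and slicing of trial recordings.

One trial is stored as a directory of plain CSV files, one per stream group,
plus a key-value metadata file:

* ``strain.csv`` — ``t, ch1, ch2, ch3, ch4`` (voltage channels @ fs_ws)
* ``imu.csv`` — ``t, ax, ay, az, gx, gy, gz, mx, my, mz`` (@ fs_ws)
* ``resp.csv`` — ``t, resp`` (reference respiratory waveform @ fs_ref_resp)
* ``ecg.csv`` — ``t, ecg`` (reference ECG @ fs_ecg)
* ``meta.txt`` — ``key=value`` lines: sampling rates, scenario, analysis
  segment, seed.

All streams are timestamped from a shared t = 0; simultaneously started,
synchronized clocks are assumed (real recordings must be pre-aligned).
Times are written with 6 decimal places; round-trips are lossless to 1e-6.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

__all__ = [
    "TrialRecording",
    "TrialFormatError",
    "save_trial",
    "load_trial",
    "extract_segment",
]

IMU_COLUMNS = ["ax", "ay", "az", "gx", "gy", "gz", "mx", "my", "mz"]
STRAIN_COLUMNS = ["ch1", "ch2", "ch3", "ch4"]


class TrialFormatError(ValueError):
    """A stream is missing, malformed, non-finite or inconsistent with the
    declared sampling rate; carries the offending stream's name."""

    def __init__(self, stream: str, message: str):
        self.stream = stream
        super().__init__(f"{stream}: {message}")


@dataclass
class TrialRecording:
    """One subject x scenario session: wearable + reference streams."""

    scenario: str
    strain: np.ndarray          # (4, n_ws) voltage channels
    imu: np.ndarray             # (9, n_ws)
    ref_resp: np.ndarray        # (n_resp,)
    ref_ecg: np.ndarray         # (n_ecg,)
    fs_ws: float
    fs_ref_resp: float
    fs_ecg: float
    analysis_segment: tuple[float, float]
    meta: dict[str, Any] = field(default_factory=dict)

    @property
    def duration_s(self) -> float:
        return self.strain.shape[1] / self.fs_ws

    def imu_channel(self, name: str) -> np.ndarray:
        return self.imu[IMU_COLUMNS.index(name)]

    def __post_init__(self) -> None:
        self.strain = np.atleast_2d(np.asarray(self.strain, dtype=float))
        self.imu = np.atleast_2d(np.asarray(self.imu, dtype=float))
        self.ref_resp = np.asarray(self.ref_resp, dtype=float)
        self.ref_ecg = np.asarray(self.ref_ecg, dtype=float)
        if self.strain.shape[0] != 4:
            raise TrialFormatError("strain", "expected 4 channels")
        if self.imu.shape[0] != 9:
            raise TrialFormatError("imu", "expected 9 channels")
        if self.strain.shape[1] != self.imu.shape[1]:
            raise TrialFormatError(
                "imu", "IMU and strain streams share the wearable clock but "
                       "differ in length")
        for name, arr in (("strain", self.strain), ("imu", self.imu),
                          ("resp", self.ref_resp), ("ecg", self.ref_ecg)):
            if not np.all(np.isfinite(arr)):
                raise TrialFormatError(name, "non-finite samples")
        dur = self.duration_s
        for name, arr, fs in (("resp", self.ref_resp, self.fs_ref_resp),
                              ("ecg", self.ref_ecg, self.fs_ecg)):
            expected = dur * fs
            if abs(arr.size - expected) > 1.0:
                raise TrialFormatError(
                    name, f"length {arr.size} inconsistent with declared "
                          f"rate {fs} Hz over {dur:.3f} s "
                          f"(expected ~{expected:.0f} samples)")


def _write_csv(path: Path, fs: float, columns: dict[str, np.ndarray]) -> None:
    n = len(next(iter(columns.values())))
    df = pd.DataFrame({"t": np.arange(n) / fs, **columns})
    df.to_csv(path, index=False, float_format="%.6f")


def save_trial(rec: TrialRecording, out_dir: str | Path) -> Path:
    """Write one trial as the CSV bundle described in the module docstring."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _write_csv(out / "strain.csv", rec.fs_ws,
               dict(zip(STRAIN_COLUMNS, rec.strain)))
    _write_csv(out / "imu.csv", rec.fs_ws, dict(zip(IMU_COLUMNS, rec.imu)))
    _write_csv(out / "resp.csv", rec.fs_ref_resp, {"resp": rec.ref_resp})
    _write_csv(out / "ecg.csv", rec.fs_ecg, {"ecg": rec.ref_ecg})
    meta = {
        "scenario": rec.scenario,
        "fs_ws": rec.fs_ws,
        "fs_ref_resp": rec.fs_ref_resp,
        "fs_ecg": rec.fs_ecg,
        "analysis_start_s": rec.analysis_segment[0],
        "analysis_end_s": rec.analysis_segment[1],
        **rec.meta,
    }
    with open(out / "meta.txt", "w") as fh:
        for k, v in meta.items():
            fh.write(f"{k}={v}\n")
    return out


def _read_meta(path: Path) -> dict[str, Any]:
    if not path.exists():
        raise TrialFormatError("meta", f"missing metadata file {path}")
    meta: dict[str, Any] = {}
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, _, value = line.partition("=")
        try:
            meta[key.strip()] = float(value.strip())
        except ValueError:
            meta[key.strip()] = value.strip()
    return meta


def _read_stream(trial_dir: Path, name: str, columns: list[str],
                 fs: float) -> np.ndarray:
    path = trial_dir / f"{name}.csv"
    if not path.exists():
        raise TrialFormatError(name, f"missing stream file {path}")
    df = pd.read_csv(path)
    missing = [c for c in ["t", *columns] if c not in df.columns]
    if missing:
        raise TrialFormatError(name, f"missing columns {missing}")
    arr = df[columns].to_numpy(dtype=float).T
    if not np.all(np.isfinite(arr)):
        raise TrialFormatError(name, "non-finite samples")
    t = df["t"].to_numpy(dtype=float)
    if len(t) > 1:
        implied_fs = (len(t) - 1) / (t[-1] - t[0])
        if abs(implied_fs - fs) > 0.01 * fs:
            raise TrialFormatError(
                name, f"timestamps imply {implied_fs:.2f} Hz but metadata "
                      f"declares {fs} Hz")
    return arr


def load_trial(trial_dir: str | Path) -> TrialRecording:
    """Load and validate one trial directory written by :func:`save_trial`."""
    trial_dir = Path(trial_dir)
    meta = _read_meta(trial_dir / "meta.txt")
    for key in ("fs_ws", "fs_ref_resp", "fs_ecg", "scenario"):
        if key not in meta:
            raise TrialFormatError("meta", f"missing key {key!r}")
    fs_ws = float(meta["fs_ws"])
    fs_resp = float(meta["fs_ref_resp"])
    fs_ecg = float(meta["fs_ecg"])
    strain = _read_stream(trial_dir, "strain", STRAIN_COLUMNS, fs_ws)
    imu = _read_stream(trial_dir, "imu", IMU_COLUMNS, fs_ws)
    resp = _read_stream(trial_dir, "resp", ["resp"], fs_resp)[0]
    ecg = _read_stream(trial_dir, "ecg", ["ecg"], fs_ecg)[0]
    duration = strain.shape[1] / fs_ws
    segment = (float(meta.get("analysis_start_s", 0.0)),
               float(meta.get("analysis_end_s", duration)))
    extra = {k: v for k, v in meta.items()
             if k not in {"scenario", "fs_ws", "fs_ref_resp", "fs_ecg",
                          "analysis_start_s", "analysis_end_s"}}
    return TrialRecording(
        scenario=str(meta["scenario"]), strain=strain, imu=imu,
        ref_resp=resp, ref_ecg=ecg, fs_ws=fs_ws, fs_ref_resp=fs_resp,
        fs_ecg=fs_ecg, analysis_segment=segment, meta=extra,
    )


def extract_segment(rec: TrialRecording, start_s: float,
                    end_s: float) -> TrialRecording:
    """Cut [start_s, end_s) out of every stream on its own clock.

    Boundaries are rounded to the nearest sample per stream.  The returned
    recording is re-timestamped from t = 0 with the full range as its
    analysis segment.
    """
    if not 0 <= start_s < end_s <= rec.duration_s + 0.5 / rec.fs_ws:
        raise ValueError(
            f"invalid segment ({start_s}, {end_s}) for a "
            f"{rec.duration_s:.3f} s recording")

    def cut(arr: np.ndarray, fs: float) -> np.ndarray:
        i0 = int(round(start_s * fs))
        i1 = int(round(end_s * fs))
        return arr[..., i0:i1]

    out = replace(
        rec,
        strain=cut(rec.strain, rec.fs_ws),
        imu=cut(rec.imu, rec.fs_ws),
        ref_resp=cut(rec.ref_resp, rec.fs_ref_resp),
        ref_ecg=cut(rec.ref_ecg, rec.fs_ecg),
        analysis_segment=(0.0, end_s - start_s),
    )
    if out.strain.shape[1] == 0:
        raise ValueError("empty segment")
    return out
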