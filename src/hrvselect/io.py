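"""Plain-text readers and writers for the pipeline's interchange formats.

Everything moves as CSV/JSON: ECG as a single voltage column (mV) with a JSON
sidecar carrying the sampling rate, tachograms as ``time_s,rr_ms``, feature
tables with the canonical 14-column header, calibration tables as tidy
``group,feature,mean,sem``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import FEATURE_NAMES
from .tachogram import ECGRecord, RPeakSeries, RRTachogram

FEATURE_TABLE_COLUMNS = ["group", "subject_id", "trial_id", *FEATURE_NAMES]


def write_ecg(ecg: ECGRecord, path: str | Path) -> None:
    """Write an ECG as single-column CSV plus a `.meta.json` sidecar."""
    path = Path(path)
    pd.DataFrame({"mV": ecg.samples}).to_csv(path, index=False)
    meta = {"fs": ecg.fs, "t0": ecg.t0, "duration": ecg.duration,
            "n_samples": int(ecg.samples.size)}
    path.with_suffix(path.suffix + ".meta.json").write_text(
        json.dumps(meta, indent=1)
    )


def read_ecg(path: str | Path, fs: float | None = None) -> ECGRecord:
    """Read an ECG CSV; fs comes from the sidecar unless given explicitly."""
    path = Path(path)
    t0 = 0.0
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    if fs is None:
        if not sidecar.exists():
            raise ValueError(f"no sampling rate: pass fs= or provide {sidecar}")
        meta = json.loads(sidecar.read_text())
        fs = float(meta["fs"])
        t0 = float(meta.get("t0", 0.0))
    samples = pd.read_csv(path).iloc[:, 0].to_numpy(dtype=float)
    return ECGRecord(samples=samples, fs=fs, t0=t0)


def write_peaks(peaks: RPeakSeries, path: str | Path) -> None:
    pd.DataFrame({"time_s": peaks.times}).to_csv(path, index=False)


def read_peaks(path: str | Path) -> RPeakSeries:
    return RPeakSeries(times=pd.read_csv(path)["time_s"].to_numpy(dtype=float))


def write_tachogram(rr: RRTachogram, path: str | Path) -> None:
    pd.DataFrame({"time_s": rr.times, "rr_ms": rr.intervals}).to_csv(
        path, index=False
    )


def read_tachogram(path: str | Path) -> RRTachogram:
    df = pd.read_csv(path)
    return RRTachogram(
        intervals=df["rr_ms"].to_numpy(dtype=float),
        times=df["time_s"].to_numpy(dtype=float),
    )


def write_feature_table(table: pd.DataFrame, path: str | Path) -> None:
    missing = [c for c in FEATURE_TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"feature table missing columns: {missing}")
    table[FEATURE_TABLE_COLUMNS].to_csv(path, index=False)


def read_feature_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path)
    missing = [c for c in ("group", *FEATURE_NAMES) if c not in table.columns]
    if missing:
        raise ValueError(f"feature table missing columns: {missing}")
    return table


def write_ranking(ranking, path: str | Path) -> None:
    """Serialise an SVMRFERanking as JSON (weights as a tidy record list)."""
    payload = {
        "rank_order": ranking.rank_order,
        "elimination_order": ranking.elimination_order,
        "C": ranking.C,
        "normalized": ranking.normalized,
        "iteration_weights": ranking.iteration_weights.to_dict(orient="records"),
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_ranking(path: str | Path):
    from .ranking import SVMRFERanking

    payload = json.loads(Path(path).read_text())
    return SVMRFERanking(
        rank_order=payload["rank_order"],
        elimination_order=payload["elimination_order"],
        iteration_weights=pd.DataFrame(
            payload["iteration_weights"],
            columns=["iteration", "model", "feature", "weight"],
        ),
        C=payload["C"],
        normalized=payload["normalized"],
    )
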