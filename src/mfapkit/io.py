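"""CSV/JSON readers and writers for the assay formats.

All CSVs are UTF-8, comma-delimited, dot-decimal, with a header row.
Numbers are serialized at full precision; rounding is applied only in
human-readable report fields.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .equilibria import IsothermFit, TitrationSeries
from .ph_sensing import RatiometricCalibration
from .timecourse import RoiTrace

__all__ = [
    "read_titration_csv",
    "write_titration_csv",
    "read_ph_sweep_csv",
    "read_kinetic_csv",
    "read_roi_csv",
    "write_result_json",
    "read_result_json",
]

TITRATION_COLUMNS = ["sample_id", "condition", "conc_uM", "replicate", "rfu"]


def read_titration_csv(path: str | Path) -> TitrationSeries:
    """Read a titration CSV (columns sample_id, condition, conc_uM,
    replicate, rfu; blank rows flagged by condition='blank')."""
    df = pd.read_csv(path)
    missing = [c for c in TITRATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    if not np.issubdtype(df["conc_uM"].dtype, np.number):
        bad = df.loc[pd.to_numeric(df["conc_uM"], errors="coerce").isna()]
        raise ValueError(
            f"{path}: non-numeric concentration in row(s) {list(bad.index[:5])}"
        )
    is_blank = df["condition"].astype(str).str.lower() == "blank"
    samples = df.loc[~is_blank]
    dup = samples.duplicated(subset=["conc_uM", "replicate"])
    if dup.any():
        raise ValueError(
            f"{path}: duplicate (conc_uM, replicate) pairs in rows "
            f"{list(samples.index[dup][:5])}"
        )

    pivot = samples.pivot(index="conc_uM", columns="replicate", values="rfu").sort_index()
    blanks = None
    blank_df = df.loc[is_blank]
    if len(blank_df):
        bpivot = blank_df.pivot(index="conc_uM", columns="replicate", values="rfu").sort_index()
        if not np.array_equal(bpivot.index.to_numpy(), pivot.index.to_numpy()):
            raise ValueError(f"{path}: blank rows do not match sample concentrations")
        blanks = bpivot.to_numpy()

    meta = {}
    if samples["sample_id"].nunique() == 1:
        meta["sample_id"] = str(samples["sample_id"].iloc[0])
    return TitrationSeries(
        analyte_conc=pivot.index.to_numpy(dtype=float),
        rfu=pivot.to_numpy(dtype=float),
        blanks=blanks,
        meta=meta,
    )


def write_titration_csv(path: str | Path, series: TitrationSeries, sample_id: str = "sample") -> None:
    rows = []
    sid = series.meta.get("sample_id", sample_id)
    for i, conc in enumerate(series.analyte_conc):
        for rep in range(series.n_replicates):
            rows.append(
                {
                    "sample_id": sid,
                    "condition": "titration",
                    "conc_uM": conc,
                    "replicate": rep,
                    "rfu": series.rfu[i, rep],
                }
            )
        if series.blanks is not None:
            for rep in range(series.blanks.shape[1]):
                rows.append(
                    {
                        "sample_id": sid,
                        "condition": "blank",
                        "conc_uM": conc,
                        "replicate": rep,
                        "rfu": series.blanks[i, rep],
                    }
                )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_ph_sweep_csv(path: str | Path) -> pd.DataFrame:
    """Read a pH sweep CSV (pH, replicate, f_blue, f_red[, blank_blue, blank_red])."""
    df = pd.read_csv(path)
    required = ["pH", "replicate", "f_blue", "f_red"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    return df


def read_kinetic_csv(path: str | Path) -> pd.DataFrame:
    """Read a kinetic CSV (time_s, rfu[, well])."""
    df = pd.read_csv(path)
    missing = [c for c in ("time_s", "rfu") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    return df


def read_roi_csv(path: str | Path) -> list[RoiTrace]:
    """Read a long-format ROI CSV (roi_id, frame, time_s, signal, background,
    stim_frame) into per-ROI traces."""
    df = pd.read_csv(path)
    required = ["roi_id", "frame", "time_s", "signal", "background", "stim_frame"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    traces = []
    for roi_id, grp in df.groupby("roi_id"):
        grp = grp.sort_values("frame")
        t = grp["time_s"].to_numpy(dtype=float)
        frame_rate = 1.0 / float(np.median(np.diff(t))) if t.size > 1 else 1.0
        traces.append(
            RoiTrace(
                time=t,
                signal=grp["signal"].to_numpy(dtype=float),
                background=grp["background"].to_numpy(dtype=float),
                stim_frame=int(grp["stim_frame"].iloc[0]),
                frame_rate=frame_rate,
                meta={"roi_id": roi_id},
            )
        )
    return traces


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (IsothermFit,)):
        return obj.to_record()
    if isinstance(obj, RatiometricCalibration):
        return obj.to_record()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_result_json(path: str | Path, payload: dict) -> None:
    Path(path).write_text(json.dumps(_jsonable(payload), indent=2) + "\n")


def read_result_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
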