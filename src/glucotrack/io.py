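"""Reading and writing session and cell-matrix files.

A session is a CSV table (one row per 1-Hz sample; columns time_s,
glucose_mM, activity_z, running_cms, vo2_lmin, vco2_lmin, temp_C) with a
JSON sidecar carrying events, the generating config echo and the seed.
Cell matrices are CSV (time_s column plus one column per cell id) with a
JSON ground-truth sidecar.  Round trips are lossless at full float
precision.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import GroundTruth, SessionRecord

SESSION_COLUMNS = {
    "time_s": "time",
    "glucose_mM": "glucose",
    "activity_z": "activity",
    "running_cms": "running",
    "vo2_lmin": "vo2",
    "vco2_lmin": "vco2",
    "temp_C": "temperature",
}


class SchemaError(ValueError):
    pass


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def sidecar_path(csv_path) -> Path:
    p = Path(csv_path)
    return p.with_suffix(".json")


def write_session(session: SessionRecord, csv_path, sidecar=None) -> None:
    df = pd.DataFrame({col: getattr(session, attr) for col, attr in SESSION_COLUMNS.items()})
    for name, arr in session.meta.get("extra_columns", {}).items():
        df[name] = arr
    df.to_csv(csv_path, index=False)
    meta = {k: v for k, v in session.meta.items() if k != "extra_columns"}
    payload = {
        "events": [[label, float(t)] for label, t in session.events],
        "meta": _jsonable(meta),
    }
    with open(sidecar or sidecar_path(csv_path), "w") as fh:
        json.dump(payload, fh, indent=1)


def read_session(csv_path, sidecar=None) -> SessionRecord:
    df = pd.read_csv(csv_path, float_precision="round_trip")
    missing = set(SESSION_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"missing columns: {sorted(missing)}")
    t = df["time_s"].to_numpy(dtype=float)
    if t.size > 1 and np.any(np.diff(t) <= 0):
        raise SchemaError("time_s is not strictly increasing")
    events, meta = [], {}
    sc = Path(sidecar or sidecar_path(csv_path))
    if sc.exists():
        with open(sc) as fh:
            payload = json.load(fh)
        events = [(e[0], float(e[1])) for e in payload.get("events", [])]
        meta = payload.get("meta", {})
    extra = [c for c in df.columns if c not in SESSION_COLUMNS]
    if extra:
        meta["extra_columns"] = {c: df[c].to_numpy() for c in extra}
    kwargs = {attr: df[col].to_numpy(dtype=float) for col, attr in SESSION_COLUMNS.items()}
    return SessionRecord(events=events, meta=meta, **kwargs)


def write_cells(cell_time, matrix, csv_path, ground_truth: GroundTruth | None = None) -> None:
    mat = np.asarray(matrix, dtype=float)
    df = pd.DataFrame(mat, columns=[f"cell_{j:04d}" for j in range(mat.shape[1])])
    df.insert(0, "time_s", np.asarray(cell_time, dtype=float))
    df.to_csv(csv_path, index=False)
    if ground_truth is not None:
        payload = {
            "cell_labels": list(ground_truth.cell_labels),
            "cell_running_labels": list(ground_truth.cell_running_labels),
            "slow_gains": _jsonable(ground_truth.slow_gains),
            "running_gains": _jsonable(ground_truth.running_gains),
            "bleach": _jsonable(ground_truth.bleach),
        }
        with open(sidecar_path(csv_path), "w") as fh:
            json.dump(payload, fh, indent=1)


def read_cells(csv_path):
    df = pd.read_csv(csv_path, float_precision="round_trip")
    if "time_s" not in df.columns:
        raise SchemaError("missing time_s column")
    t = df["time_s"].to_numpy(dtype=float)
    ids = [c for c in df.columns if c != "time_s"]
    return t, df[ids].to_numpy(dtype=float), ids


def read_ground_truth(json_path) -> GroundTruth:
    with open(json_path) as fh:
        payload = json.load(fh)
    return GroundTruth(
        cell_labels=payload["cell_labels"],
        cell_running_labels=payload["cell_running_labels"],
        slow_gains=np.asarray(payload["slow_gains"], dtype=float),
        running_gains=np.asarray(payload["running_gains"], dtype=float),
        bleach=payload.get("bleach", {}),
    )
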