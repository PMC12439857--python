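"""CSV/JSON schemas and atomic file I/O for every pipeline stage.

All tables are UTF-8 CSV with a mandatory header; floats are written with 6
significant digits; writes go through a temporary file and an atomic
rename.  Readers type-check required columns and enforce the long-format
signal invariants (strictly increasing, duplicate-free times per case and
channel).
"""

from __future__ import annotations

import hashlib
import json
import os
import tempfile
from typing import Optional

import numpy as np
import pandas as pd


class SchemaError(ValueError):
    """Raised when a table violates its documented schema."""


SCHEMAS: dict[str, list[str]] = {
    "clinical": ["case_id", "age", "sex", "height", "weight", "asa_class",
                 "surgery_type", "surgical_approach", "fev1_fvc_ratio",
                 "fvc_pct_predicted"],
    "signals": ["case_id", "channel", "time_s", "value"],
    "abga": ["case_id", "recorded_time_s", "paco2"],
    "events": ["event_id", "case_id", "recorded_time_s", "status",
               "estimated_draw_time_s", "trigger_time_s", "window_start_s",
               "window_end_s", "target_paco2"],
    "predictions": ["event_id", "case_id", "actual", "predicted", "model",
                    "fold"],
}


def _atomic_write(path: str, write_fn) -> None:
    d = os.path.dirname(os.path.abspath(path))
    os.makedirs(d, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=d, suffix=".tmp")
    try:
        with os.fdopen(fd, "w", encoding="utf-8", newline="") as fh:
            write_fn(fh)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def write_table(df: pd.DataFrame, path: str) -> None:
    """Atomic CSV write with 6-significant-digit floats."""
    _atomic_write(path, lambda fh: df.to_csv(fh, index=False,
                                             float_format="%.6g"))


def read_table(path: str, kind: str) -> pd.DataFrame:
    """Read and schema-check one of the documented tables."""
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    required = SCHEMAS[kind]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    if kind == "signals":
        _check_signals(df, path)
    if kind == "abga":
        for col in ("recorded_time_s", "paco2"):
            if not pd.api.types.is_numeric_dtype(df[col]):
                raise SchemaError(f"{path}: column {col} must be numeric")
    return df


def _check_signals(df: pd.DataFrame, path: str) -> None:
    if not pd.api.types.is_numeric_dtype(df["time_s"]):
        raise SchemaError(f"{path}: time_s must be numeric")
    if not pd.api.types.is_numeric_dtype(df["value"]):
        raise SchemaError(f"{path}: value must be numeric")
    t = df["time_s"].to_numpy()
    grp = df.groupby(["case_id", "channel"], sort=False).indices
    for key, idx in grp.items():
        tt = t[idx]
        bad = np.flatnonzero(np.diff(tt) <= 0)
        if bad.size:
            raise SchemaError(
                f"{path}: non-increasing or duplicate time for {key} "
                f"near row {idx[bad[0] + 1]}")


def write_json(obj: dict, path: str) -> None:
    _atomic_write(path, lambda fh: fh.write(
        json.dumps(obj, sort_keys=True, indent=2)))


def read_json(path: str) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        return json.load(fh)


def file_sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(path: str, config_dict: dict, seed: int,
                   files: Optional[list[str]] = None,
                   counts: Optional[dict] = None) -> None:
    """Reproducibility manifest: config, seed, output checksums, counts."""
    manifest = {"config": config_dict, "seed": seed,
                "files": {}, "counts": counts or {}}
    for f in files or []:
        if os.path.exists(f):
            manifest["files"][os.path.basename(f)] = file_sha256(f)
    write_json(manifest, path)
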