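"""Trial-table and report I/O.

Trial tables are plain CSV (header row, UTF-8, '.' decimal) with the exact
column set of :data:`tachometric.design.TRIAL_COLUMNS`. Reading validates
the schema and reports malformed rows with their file line numbers; writing
round-trips all fields losslessly.
"""

from __future__ import annotations

import hashlib
import json
import math
from pathlib import Path

import numpy as np
import pandas as pd

from .design import TRIAL_COLUMNS

__all__ = ["ParseError", "read_trials", "write_trials", "write_report",
           "jsonify", "config_hash"]

_NUMERIC = ["session", "block", "trial_in_block", "soa_ms", "gap_ms",
            "fixation_ms", "rt_ms", "correct", "on_time"]


class ParseError(ValueError):
    """Schema or row-level failure while reading a trial table."""


def read_trials(path) -> pd.DataFrame:
    """Read a trial table, enforcing the canonical schema.

    Raises :class:`ParseError` naming any missing columns, or listing the
    1-based file line numbers of rows whose numeric fields fail to parse.
    An empty file with a header yields an empty table.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required columns: {', '.join(missing)}")
    bad_lines: list[int] = []
    for col in _NUMERIC:
        raw = df[col].str.strip()
        num = pd.to_numeric(raw, errors="coerce")
        bad = num.isna() & (raw != "")
        if bad.any():
            bad_lines.extend((df.index[bad] + 2).tolist())  # +2: header + 1-base
        df[col] = num
    if bad_lines:
        raise ParseError(f"{path}: malformed numeric values on lines "
                         f"{sorted(set(bad_lines))}")
    df["is_practice"] = df["is_practice"].str.strip().str.lower() \
        .map({"true": True, "false": False, "1": True, "0": False})
    df["response"] = df["response"].replace("", None)
    return df[TRIAL_COLUMNS]


def write_trials(records: pd.DataFrame, path) -> None:
    """Write a trial table in the canonical column order."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    records[TRIAL_COLUMNS].to_csv(path, index=False)


def jsonify(obj):
    """Recursively convert numpy/pandas scalars and containers to JSON-safe
    builtins; non-finite floats become the strings "inf"/"-inf"/"nan" so the
    output parses as strict JSON with the sentinels retained."""
    if isinstance(obj, dict):
        return {str(k): jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, np.ndarray, pd.Series)):
        return [jsonify(v) for v in obj]
    if isinstance(obj, pd.DataFrame):
        return [jsonify(r) for r in obj.to_dict(orient="records")]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (float, np.floating)):
        x = float(obj)
        if math.isnan(x):
            return "nan"
        if math.isinf(x):
            return "inf" if x > 0 else "-inf"
        return x
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def config_hash(config: dict) -> str:
    """Stable short hash of a configuration tree."""
    blob = json.dumps(jsonify(config), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_report(report: dict, path) -> None:
    """Serialize a report deterministically (sorted keys, fixed layout)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(jsonify(report), sort_keys=True, indent=2,
                               allow_nan=False) + "\n")
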