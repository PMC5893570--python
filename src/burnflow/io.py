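"""Plain-text I/O for cases, fire events, configs and reports."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

from .synth import FireEvent, SyntheticCase

__all__ = [
    "CASE_COLUMNS",
    "write_case_csv",
    "read_case_csv",
    "write_fire_events_csv",
    "read_fire_events_csv",
    "load_yaml_config",
    "write_json_report",
]

#: Canonical per-case daily CSV schema (SWE/Q optional on read).
CASE_COLUMNS = ("date", "P_mm", "T_C", "Hr_day", "SWE_mm", "Q_mm")
_COL_TO_FIELD = {"P_mm": "P", "T_C": "T", "Hr_day": "Hr_day",
                 "SWE_mm": "SWE", "Q_mm": "Q"}
_FIELD_TO_COL = {v: k for k, v in _COL_TO_FIELD.items()}


def write_case_csv(daily: pd.DataFrame, path) -> None:
    """Write a daily record to the canonical CSV schema."""
    out = pd.DataFrame({"date": daily.index.strftime("%Y-%m-%d")})
    for col, fld in _COL_TO_FIELD.items():
        if fld in daily.columns:
            out[col] = daily[fld].to_numpy()
    out.to_csv(path, index=False, float_format="%.10g")


def read_case_csv(path) -> pd.DataFrame:
    """Read a daily record; returns columns P, T, Hr_day and, when
    present, SWE and Q, indexed by date.

    Missing optional columns (SWE_mm, Q_mm) are tolerated — downstream
    steps needing them degrade gracefully — but the mandatory schema
    columns must be present, and dates must be strictly increasing.
    """
    raw = pd.read_csv(path)
    required = ["date", "P_mm", "T_C", "Hr_day"]
    missing = [c for c in required if c not in raw.columns]
    if missing:
        raise ValueError(f"case CSV {path} lacks columns: {missing}")
    idx = pd.to_datetime(raw["date"])
    if not idx.is_monotonic_increasing or idx.duplicated().any():
        raise ValueError(f"case CSV {path}: dates must be strictly increasing")
    data = {}
    for col, fld in _COL_TO_FIELD.items():
        if col in raw.columns:
            data[fld] = raw[col].to_numpy(dtype=float)
    return pd.DataFrame(data, index=pd.DatetimeIndex(idx, name="date"))


def write_fire_events_csv(cases: Iterable, path) -> None:
    """Write fire events (one row per case) to CSV.

    Accepts :class:`~burnflow.synth.SyntheticCase` objects or
    ``(case_id, FireEvent)`` pairs.
    """
    rows = []
    for item in cases:
        if isinstance(item, SyntheticCase):
            cid, ev = item.case_id, item.fire
        else:
            cid, ev = item
        wf = ev.watershed_fractions
        rows.append({
            "case_id": cid,
            "fire_date": ev.date.strftime("%Y-%m-%d"),
            "BAR": ev.bar,
            "frac_unburned": wf.get("unburned", 0.0),
            "frac_low": wf.get("low", 0.0),
            "frac_moderate": wf.get("moderate", 0.0),
            "frac_high": wf.get("high", 0.0),
            "frac_greenness": wf.get("greenness", 0.0),
        })
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.10g")


def read_fire_events_csv(path) -> dict[str, FireEvent]:
    """Read fire events back into FireEvent objects keyed by case id."""
    raw = pd.read_csv(path)
    events = {}
    for _, row in raw.iterrows():
        bar = float(row["BAR"])
        classes = {"unburned": row["frac_unburned"], "low": row["frac_low"],
                   "moderate": row["frac_moderate"], "high": row["frac_high"],
                   "greenness": row["frac_greenness"]}
        if bar > 0:
            mix = {k: float(v) / bar for k, v in classes.items()}
            total = sum(mix.values())
            mix = {k: v / total for k, v in mix.items()}
        else:
            mix = {"unburned": 1.0, "low": 0.0, "moderate": 0.0,
                   "high": 0.0, "greenness": 0.0}
        events[str(row["case_id"])] = FireEvent(
            date=pd.Timestamp(row["fire_date"]), bar=bar, severity_mix=mix)
    return events


def load_yaml_config(path) -> dict:
    """Load a run-configuration mapping from YAML."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, Mapping):
        raise ValueError(f"config {path} must be a YAML mapping")
    return dict(cfg)


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, pd.Series):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, pd.DataFrame):
        return {str(c): _jsonable(obj[c]) for c in obj.columns}
    if isinstance(obj, (np.ndarray, list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return v if np.isfinite(v) else None
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, (np.bool_, bool)):
        return bool(obj)
    if isinstance(obj, (pd.Period, pd.Timestamp)):
        return str(obj)
    return obj


def write_json_report(report, path) -> None:
    """Serialize a result object (dataclass/mapping) to pretty JSON.

    Written atomically: to a temp file first, then renamed into place.
    """
    path = Path(path)
    tmp = path.with_suffix(path.suffix + ".tmp")
    with open(tmp, "w") as fh:
        json.dump(_jsonable(report), fh, indent=2)
    tmp.replace(path)
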