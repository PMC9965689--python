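"""CSV/JSON readers and writers and configuration loading.

Fixed file dialect: comma-separated UTF-8 CSV with a header row, "." decimal
separator, ISO-8601 UTC timestamps.  Numeric columns are written with six
decimals.
"""

from __future__ import annotations

import datetime as _dt
import json
import warnings
from dataclasses import fields as _dc_fields
from pathlib import Path
from typing import Sequence

import pandas as pd

from .core_model import ProbePhysics
from .errors import ConfigError, ReadingsFormatError
from .freeze_thaw import FreezeThawRecord, SensorReading

READINGS_COLUMNS = ["timestamp", "voltage_v", "temp_c"]
RECORDS_COLUMNS = ["timestamp", "theta_pct", "delta_pct", "sigma_pct_per_min", "frozen"]
_TS_FORMAT = "%Y-%m-%dT%H:%M:%SZ"


def _format_ts(ts: _dt.datetime) -> str:
    if ts.tzinfo is None:
        ts = ts.replace(tzinfo=_dt.timezone.utc)
    return ts.astimezone(_dt.timezone.utc).strftime(_TS_FORMAT)


def read_readings_csv(path: str | Path) -> list[SensorReading]:
    """Read a sensor-readings CSV into a timestamp-sorted series.

    The header must be exactly ``timestamp,voltage_v,temp_c``.  Out-of-order
    rows are sorted with a warning; duplicate timestamps and unparseable rows
    raise :class:`ReadingsFormatError` naming the offending (1-based data)
    row.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str)
    if list(df.columns) != READINGS_COLUMNS:
        raise ReadingsFormatError(
            f"expected header {','.join(READINGS_COLUMNS)!r}, got {','.join(df.columns)!r}"
        )
    timestamps: list[_dt.datetime] = []
    voltages: list[float] = []
    temps: list[float] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            ts = pd.Timestamp(row.timestamp)
            if ts.tzinfo is None:
                ts = ts.tz_localize("UTC")
            timestamps.append(ts.to_pydatetime())
            voltages.append(float(row.voltage_v))
            temps.append(float(row.temp_c))
        except (ValueError, TypeError) as exc:
            raise ReadingsFormatError(f"unparseable row {i}: {exc}") from exc
    order = sorted(range(len(timestamps)), key=lambda k: timestamps[k])
    if order != list(range(len(timestamps))):
        warnings.warn(f"{path.name}: rows out of timestamp order; sorted", UserWarning)
    seen: dict[_dt.datetime, int] = {}
    for i, ts in enumerate(timestamps, start=1):
        if ts in seen:
            raise ReadingsFormatError(
                f"duplicate timestamp at row {i} (first seen at row {seen[ts]})"
            )
        seen[ts] = i
    return [
        SensorReading(timestamp=timestamps[k], U=voltages[k], temp=temps[k])
        for k in order
    ]


def write_readings_csv(series: Sequence[SensorReading], path: str | Path) -> None:
    """Write a sensor-readings CSV (inverse of :func:`read_readings_csv`)."""
    df = pd.DataFrame(
        {
            "timestamp": [_format_ts(r.timestamp) for r in series],
            "voltage_v": [f"{r.U:.6f}" for r in series],
            "temp_c": [f"{r.temp:.6f}" for r in series],
        }
    )
    df.to_csv(path, index=False)


def write_records_csv(records: Sequence[FreezeThawRecord], path: str | Path) -> None:
    """Write processed freeze–thaw records; empty input yields a header-only file."""
    df = pd.DataFrame(
        {
            "timestamp": [_format_ts(r.timestamp) for r in records],
            "theta_pct": [f"{r.theta_x:.6f}" for r in records],
            "delta_pct": [f"{r.delta:.6f}" for r in records],
            "sigma_pct_per_min": [f"{r.sigma:.6f}" for r in records],
            "frozen": [r.frozen for r in records],
        },
        columns=RECORDS_COLUMNS,
    )
    df.to_csv(path, index=False)


def read_records_csv(path: str | Path) -> list[FreezeThawRecord]:
    """Read back a processed-records CSV (round-trip of :func:`write_records_csv`)."""
    df = pd.read_csv(path)
    if list(df.columns) != RECORDS_COLUMNS:
        raise ReadingsFormatError(
            f"expected header {','.join(RECORDS_COLUMNS)!r}, got {','.join(df.columns)!r}"
        )
    out = []
    for row in df.itertuples(index=False):
        ts = pd.Timestamp(row.timestamp)
        if ts.tzinfo is None:
            ts = ts.tz_localize("UTC")
        out.append(
            FreezeThawRecord(
                timestamp=ts.to_pydatetime(),
                theta_x=float(row.theta_pct),
                delta=float(row.delta_pct),
                sigma=float(row.sigma_pct_per_min),
                frozen=bool(row.frozen),
            )
        )
    return out


def write_summary_json(summary: dict, path: str | Path) -> None:
    """Write a rate-summary (or any plain dict) as indented JSON."""
    Path(path).write_text(json.dumps(summary, indent=2) + "\n", encoding="utf-8")


_PROBE_CONFIG_KEYS = {
    "frequency_hz", "z_line_ohm", "beta0", "amplitude_v", "k_geo_m",
    "eps_l", "eps_s", "eps_g",
}


def load_probe_config(path: str | Path) -> tuple[ProbePhysics, dict[str, float]]:
    """Load probe/circuit constants from a key-value JSON file.

    Returns the :class:`ProbePhysics` plus a dict of the phase permittivities
    (``eps_g``, ``eps_l``, ``eps_s``).  Unknown keys are rejected.
    """
    try:
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise ConfigError(f"not valid JSON: {exc}") from exc
    if not isinstance(payload, dict):
        raise ConfigError("probe config must be a JSON object")
    unknown = set(payload) - _PROBE_CONFIG_KEYS
    if unknown:
        raise ConfigError(f"unknown probe config keys: {sorted(unknown)}")
    defaults = ProbePhysics()
    import math

    physics = ProbePhysics(
        k_geo=float(payload.get("k_geo_m", defaults.k_geo)),
        w=2.0 * math.pi * float(payload["frequency_hz"]) if "frequency_hz" in payload
        else defaults.w,
        ZL=float(payload.get("z_line_ohm", defaults.ZL)),
        beta0=float(payload.get("beta0", defaults.beta0)),
        A=float(payload.get("amplitude_v", defaults.A)),
    )
    eps = {
        "eps_g": float(payload.get("eps_g", 1.0)),
        "eps_l": float(payload.get("eps_l", 81.0)),
        "eps_s": float(payload.get("eps_s", 3.0)),
    }
    return physics, eps


def dataclass_from_dict(cls, payload: dict, what: str):
    """Build a dataclass from a dict, rejecting unknown keys."""
    known = {f.name for f in _dc_fields(cls)}
    unknown = set(payload) - known
    if unknown:
        raise ConfigError(f"unknown {what} keys: {sorted(unknown)}")
    return cls(**payload)
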