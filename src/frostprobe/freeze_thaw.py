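"""Freeze–thaw processing pipeline.

Turns a (timestamp, voltage, ambient temperature) series into per-sample
volumetric water content, volumetric ice content and ice freeze–thaw rate:

1. a sample is *frozen* when ambient temperature is at or below the
   freezing point;
2. the pre-freeze baseline water content ``theta0`` is the mean calibrated
   water content over the last ``baseline_window`` samples strictly before
   freezing begins (re-established for every distinct freeze event);
3. during freezing, ice content is the drop in water content scaled by the
   ice/water density ratio: ``delta = (theta0 - theta_x) * density_ratio``;
4. the freeze–thaw rate is the absolute forward difference of ice content
   per minute, zero by convention at the series end.
"""

from __future__ import annotations

import datetime as _dt
import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .calibration import CalibrationModel, apply_calibration
from .errors import DomainError, InsufficientDataError, MissingBaselineError

logger = logging.getLogger(__name__)

#: Human-readable labels for the four summary statistics.
RATE_TABLE_LABELS = {
    "mean": "Mean Value",
    "sd": "Standard Deviation",
    "min": "Minimum Value",
    "max": "Maximum Value",
}


@dataclass(frozen=True)
class SensorReading:
    """One timestamped sample of probe voltage and ambient temperature."""

    timestamp: _dt.datetime
    U: float
    temp: float


@dataclass(frozen=True)
class PipelineConfig:
    """Tunable constants of the freeze–thaw pipeline.

    ``density_ratio`` is rho_ice / rho_water = 917/1000 by default; the
    freezing comparison is inclusive (temp <= freezing_point is frozen).
    """

    freezing_point: float = 0.0
    density_ratio: float = 0.917
    baseline_window: int = 3
    clamp_negative_ice: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.density_ratio <= 1.0:
            raise DomainError(f"density_ratio must be in (0, 1], got {self.density_ratio!r}")
        if self.baseline_window < 1:
            raise DomainError(f"baseline_window must be >= 1, got {self.baseline_window!r}")


@dataclass(frozen=True)
class FreezeThawRecord:
    """Per-sample pipeline output."""

    timestamp: _dt.datetime
    theta_x: float  # volumetric water content, %
    delta: float  # volumetric ice content, %
    sigma: float  # ice freeze-thaw rate, %/min
    frozen: bool


def _epoch_seconds(ts: _dt.datetime) -> float:
    if ts.tzinfo is None:
        ts = ts.replace(tzinfo=_dt.timezone.utc)
    return ts.timestamp()


def detect_frozen(
    temps: Sequence[float] | np.ndarray, freezing_point: float = 0.0
) -> np.ndarray:
    """Boolean frozen flags: True wherever temperature <= freezing point."""
    return np.asarray(temps, dtype=float) <= freezing_point


def baseline_theta0(
    series: Sequence[SensorReading],
    model: CalibrationModel,
    config: PipelineConfig = PipelineConfig(),
) -> float:
    """Pre-freeze baseline water content theta0 (%).

    Mean calibrated water content over the last ``baseline_window`` samples
    strictly before the first frozen sample (all samples if the series never
    freezes).

    Raises
    ------
    MissingBaselineError
        If the series is frozen from its first sample.
    """
    if not series:
        raise InsufficientDataError("empty series")
    frozen = detect_frozen([r.temp for r in series], config.freezing_point)
    first_frozen = int(np.argmax(frozen)) if frozen.any() else len(series)
    if first_frozen == 0:
        raise MissingBaselineError(
            "series is frozen from the first sample; supply theta0 explicitly"
        )
    window = series[max(0, first_frozen - config.baseline_window) : first_frozen]
    return float(np.mean([apply_calibration(r.U, model).theta for r in window]))


def ice_content(
    theta0: float,
    theta_x: float,
    density_ratio: float = 0.917,
    clamp: bool = True,
) -> float:
    """Volumetric ice content ``delta = (theta0 - theta_x) * density_ratio`` (%).

    A negative raw value (water content above baseline) is clamped to 0 when
    ``clamp`` is set; each clamp is logged.
    """
    for name, value in (("theta0", theta0), ("theta_x", theta_x)):
        if not 0.0 <= value <= 100.0:
            raise DomainError(f"{name} must be in [0, 100] %, got {value!r}")
    raw = (theta0 - theta_x) * density_ratio
    if raw < 0.0 and clamp:
        logger.debug("negative ice content %.4f%% clamped to 0", raw)
        return 0.0
    return raw


def freeze_thaw_rate(
    timestamps: Sequence[_dt.datetime],
    deltas: Sequence[float] | np.ndarray,
) -> np.ndarray:
    """Ice freeze–thaw rate sigma (%/min) for each sample.

    Forward difference ``|delta[i+1] - delta[i]| / dt_minutes``; the last
    sample's rate is 0 by convention.  Timestamps must strictly increase.
    """
    if len(timestamps) != len(deltas):
        raise DomainError("timestamps and deltas must have equal length")
    t = np.asarray([_epoch_seconds(ts) for ts in timestamps], dtype=float)
    d = np.asarray(deltas, dtype=float)
    sigma = np.zeros_like(d)
    if len(d) < 2:
        return sigma
    dt_min = np.diff(t) / 60.0
    bad = np.nonzero(dt_min <= 0)[0]
    if bad.size:
        raise DomainError(
            f"timestamps must strictly increase (violation at sample {bad[0] + 1})"
        )
    sigma[:-1] = np.abs(np.diff(d)) / dt_min
    return sigma


def process_series(
    series: Sequence[SensorReading],
    model: CalibrationModel,
    config: PipelineConfig = PipelineConfig(),
    theta0: float | None = None,
) -> list[FreezeThawRecord]:
    """Run the full pipeline over a sensor series.

    Ice content is 0 whenever the sample is not frozen.  The baseline is
    re-established at every unfrozen -> frozen transition from the samples
    immediately preceding it (unless an explicit ``theta0`` overrides it for
    all events); each baseline is logged.

    Raises
    ------
    MissingBaselineError
        If a freeze event starts at the first sample and no ``theta0`` is
        given.
    DomainError
        On non-increasing timestamps.
    """
    if not series:
        return []
    timestamps = [r.timestamp for r in series]
    t = [_epoch_seconds(ts) for ts in timestamps]
    for i in range(1, len(t)):
        if t[i] <= t[i - 1]:
            raise DomainError(f"timestamps must strictly increase (violation at sample {i})")

    frozen = detect_frozen([r.temp for r in series], config.freezing_point)
    theta_x = np.empty(len(series))
    clamped_theta = 0
    for i, r in enumerate(series):
        cal = apply_calibration(r.U, model)
        theta_x[i] = cal.theta
        clamped_theta += cal.clamped
    if clamped_theta:
        logger.info("%d calibrated water contents clamped to [0, 100]%%", clamped_theta)

    delta = np.zeros(len(series))
    clamped_ice = 0
    event_theta0 = math.nan
    for i in range(len(series)):
        if not frozen[i]:
            continue
        if i == 0 or not frozen[i - 1]:  # new freeze event: (re-)baseline
            if theta0 is not None:
                event_theta0 = theta0
            else:
                window = theta_x[max(0, i - config.baseline_window) : i]
                if window.size == 0:
                    raise MissingBaselineError(
                        "series is frozen from the first sample; supply theta0 explicitly"
                    )
                event_theta0 = float(np.mean(window))
            logger.info(
                "freeze event at sample %d: baseline theta0 = %.4f%%", i, event_theta0
            )
        raw = (event_theta0 - theta_x[i]) * config.density_ratio
        if raw < 0.0 and config.clamp_negative_ice:
            clamped_ice += 1
            raw = 0.0
        delta[i] = raw
    if clamped_ice:
        logger.info("%d negative ice contents clamped to 0", clamped_ice)

    sigma = freeze_thaw_rate(timestamps, delta)
    return [
        FreezeThawRecord(
            timestamp=timestamps[i],
            theta_x=float(theta_x[i]),
            delta=float(delta[i]),
            sigma=float(sigma[i]),
            frozen=bool(frozen[i]),
        )
        for i in range(len(series))
    ]


def summarize_rates(records: Sequence[FreezeThawRecord]) -> dict[str, float]:
    """Summary statistics of the freeze–thaw rate over a processed series.

    Returns ``{"mean", "sd", "min", "max"}`` in %/min; the standard deviation
    uses the n-1 (sample) denominator.
    """
    if len(records) < 2:
        raise InsufficientDataError(
            f"rate summary needs >= 2 records, got {len(records)}"
        )
    sigma = np.asarray([r.sigma for r in records], dtype=float)
    return {
        "mean": float(np.mean(sigma)),
        "sd": float(np.std(sigma, ddof=1)),
        "min": float(np.min(sigma)),
        "max": float(np.max(sigma)),
    }


def format_rate_table(summary: dict[str, float]) -> str:
    """Human-readable one-row table of the rate summary (%/min)."""
    lines = [
        f"{RATE_TABLE_LABELS[key]}: {summary[key]:.5f} %/min"
        for key in ("mean", "sd", "min", "max")
    ]
    return "\n".join(lines)
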