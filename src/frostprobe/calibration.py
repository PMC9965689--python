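"""Linear voltage -> volumetric-water-content calibration.

The deployed relationship is ``theta = slope_k * U + intercept_b`` with
coefficients obtained by ordinary least squares against drying-method ground
truth, fitted and stored per species/instrument.
"""

from __future__ import annotations

import datetime as _dt
import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
from scipy import stats

from .errors import CalibrationFileError, DomainError, InsufficientDataError


class DegenerateCalibrationWarning(UserWarning):
    """The fitted slope is (numerically) zero: the sensor does not respond."""


@dataclass(frozen=True)
class CalibrationPair:
    """One calibration observation: sensor voltage vs drying-method truth."""

    U: float
    theta: float

    def __post_init__(self) -> None:
        if self.U < 0:
            raise DomainError(f"voltage must be >= 0, got {self.U!r}")
        if not 0.0 <= self.theta <= 100.0:
            raise DomainError(f"theta must be in [0, 100] %, got {self.theta!r}")


@dataclass(frozen=True)
class CalibrationModel:
    """Fitted linear model ``theta(U) = slope_k * U + intercept_b``."""

    species: str
    slope_k: float  # %/V
    intercept_b: float  # %
    r_squared: float
    fitted_at: str | None = field(default=None)

    def __post_init__(self) -> None:
        if not (math.isfinite(self.slope_k) and math.isfinite(self.intercept_b)):
            raise DomainError("calibration coefficients must be finite")
        if not -1e-9 <= self.r_squared <= 1.0 + 1e-9:
            raise DomainError(f"r_squared must lie in [0, 1], got {self.r_squared!r}")
        if self.slope_k == 0.0:
            warnings.warn(
                "fitted slope is zero: voltage carries no water-content signal",
                DegenerateCalibrationWarning,
                stacklevel=3,
            )


class CalibratedTheta(NamedTuple):
    """Calibrated water content with an out-of-range clamp audit flag."""

    theta: float
    clamped: bool


def fit_calibration(pairs: Sequence[CalibrationPair], species: str) -> CalibrationModel:
    """Ordinary least squares of water content on voltage.

    Parameters
    ----------
    pairs
        At least three (voltage, water-content) observations with non-constant
        voltage.
    species
        Label keying the model (one calibration per species/instrument).

    Returns
    -------
    CalibrationModel
        Slope in %/V, intercept in % and the coefficient of determination.
    """
    if len(pairs) < 3:
        raise InsufficientDataError(
            f"calibration needs >= 3 pairs, got {len(pairs)}"
        )
    U = np.asarray([p.U for p in pairs], dtype=float)
    theta = np.asarray([p.theta for p in pairs], dtype=float)
    if np.ptp(U) == 0.0:
        raise InsufficientDataError("all calibration voltages identical: slope undefined")
    fit = stats.linregress(U, theta)
    # R^2 from residuals so the zero-variance-theta case (perfect flat fit,
    # where rvalue is nan) degrades gracefully to 1.
    resid = theta - (fit.slope * U + fit.intercept)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((theta - theta.mean()) ** 2))
    if ss_tot == 0.0:
        r_squared = 1.0 if np.isclose(ss_res, 0.0) else 0.0
    else:
        r_squared = max(0.0, min(1.0, 1.0 - ss_res / ss_tot))
    fitted_at = _dt.datetime.now(_dt.timezone.utc).strftime("%Y-%m-%dT%H:%M:%SZ")
    return CalibrationModel(
        species=species,
        slope_k=float(fit.slope),
        intercept_b=float(fit.intercept),
        r_squared=r_squared,
        fitted_at=fitted_at,
    )


def apply_calibration(
    U: float, model: CalibrationModel, clamp: bool = True
) -> CalibratedTheta:
    """Convert a voltage to volumetric water content (%).

    Raw values outside [0, 100] are clamped (field voltages drift slightly
    outside the calibrated span); the flag records that this happened.
    """
    raw = model.slope_k * float(U) + model.intercept_b
    if clamp and not 0.0 <= raw <= 100.0:
        return CalibratedTheta(theta=min(max(raw, 0.0), 100.0), clamped=True)
    return CalibratedTheta(theta=raw, clamped=False)


_REQUIRED_FIELDS = {"species": str, "slope_k": float, "intercept_b": float, "r_squared": float}


def save_calibration(model: CalibrationModel, path: str | Path) -> None:
    """Persist a calibration model as JSON."""
    payload = {
        "species": model.species,
        "slope_k": model.slope_k,
        "intercept_b": model.intercept_b,
        "r_squared": model.r_squared,
        "fitted_at": model.fitted_at,
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")


def load_calibration(path: str | Path) -> CalibrationModel:
    """Load a calibration model, validating every field.

    Raises
    ------
    CalibrationFileError
        If the file is not valid JSON, a required field is missing or has the
        wrong type, or a field violates a model invariant.
    """
    try:
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise CalibrationFileError(f"not valid JSON: {exc}") from exc
    if not isinstance(payload, dict):
        raise CalibrationFileError("top-level JSON value must be an object")
    for name, typ in _REQUIRED_FIELDS.items():
        if name not in payload:
            raise CalibrationFileError(f"missing required field {name!r}")
        value = payload[name]
        if typ is float and isinstance(value, bool):
            raise CalibrationFileError(f"field {name!r} must be a number")
        if typ is float and not isinstance(value, (int, float)):
            raise CalibrationFileError(f"field {name!r} must be a number")
        if typ is str and not isinstance(value, str):
            raise CalibrationFileError(f"field {name!r} must be a string")
    try:
        return CalibrationModel(
            species=payload["species"],
            slope_k=float(payload["slope_k"]),
            intercept_b=float(payload["intercept_b"]),
            r_squared=float(payload["r_squared"]),
            fitted_at=payload.get("fitted_at"),
        )
    except DomainError as exc:
        raise CalibrationFileError(str(exc)) from exc
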