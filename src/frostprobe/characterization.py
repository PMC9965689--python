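"""Sensor characterization arithmetic.

Closed-form figures of merit of the impedance measurement circuit: voltage ->
ice-content sensitivity, resolution, accuracy, environmental error bounds,
radial energy index, conductivity response and electrode coverage area.

The characterized report chain deliberately uses the two-decimal *rounded*
sensitivity factor downstream (resolution, environmental bounds), because the
deployed figures were derived with the rounded value; the unrounded factor is
always returned alongside.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import NamedTuple

from .errors import DomainError


class CharacterizationWarning(UserWarning):
    """A characterization quantity is degenerate or outside its nominal range."""


@dataclass(frozen=True)
class SensorSpec:
    """Static characteristics of the measurement chain.

    Defaults are the characterized values: a 1.574 V output span over the
    0-100 % ice-content range and an ADC step of 0.0008 V.
    """

    full_span_v: float = 1.574
    range_pct: float = 100.0
    adc_lsb_v: float = 0.0008

    def __post_init__(self) -> None:
        if not self.full_span_v > 0:
            raise DomainError(f"full_span_v must be > 0, got {self.full_span_v!r}")
        if not self.range_pct > 0:
            raise DomainError(f"range_pct must be > 0, got {self.range_pct!r}")
        if self.adc_lsb_v < 0:
            raise DomainError(f"adc_lsb_v must be >= 0, got {self.adc_lsb_v!r}")


@dataclass(frozen=True)
class EnergyIndexInputs:
    """Reference/test voltages for the radial energy index."""

    Ux: float  # with the test branch in place
    U0: float  # probe in air
    Uc: float  # probe in water

    def __post_init__(self) -> None:
        if self.U0 == self.Uc:
            raise DomainError("air and water reference voltages must differ")


@dataclass(frozen=True)
class ElectrodeGeometry:
    """Ring-electrode geometry for the coverage-area formula.

    ``pi_value`` defaults to full precision; pass 3.14 to reproduce the
    characterized coverage figures digit-for-digit.
    """

    ring_dim_mm: float
    width_mm: float = 12.6
    pi_value: float = math.pi

    def __post_init__(self) -> None:
        if not 10.0 <= self.ring_dim_mm <= 40.0:
            raise DomainError(
                f"ring_dim_mm must be within the adjustable 10-40 mm range, got {self.ring_dim_mm!r}"
            )
        if self.width_mm < 0:
            raise DomainError(f"width_mm must be >= 0, got {self.width_mm!r}")


class Sensitivity(NamedTuple):
    """Sensitivity factor in %/V: rounded (2 dp) and raw."""

    rounded: float
    raw: float


class EnvErrorBounds(NamedTuple):
    """Water-content error interval from a voltage-fluctuation interval (%)."""

    low: float
    high: float
    half_width: float


def sensitivity_factor(spec: SensorSpec = SensorSpec()) -> Sensitivity:
    """Ice-content change per volt of output: ``range_pct / full_span_v``."""
    raw = spec.range_pct / spec.full_span_v
    return Sensitivity(rounded=round(raw, 2), raw=raw)


def resolution(spec: SensorSpec = SensorSpec()) -> float:
    """Smallest resolvable ice-content change (%): sensitivity x ADC step.

    Uses the rounded sensitivity factor, then rounds the product to two
    decimals.  A zero ADC step yields a (flagged) degenerate 0 % resolution.
    """
    if spec.adc_lsb_v == 0:
        warnings.warn(
            "adc_lsb_v is 0: resolution degenerates to 0%", CharacterizationWarning,
            stacklevel=2,
        )
    return round(sensitivity_factor(spec).rounded * spec.adc_lsb_v, 2)


def accuracy_pm(full_range_error_pct: float) -> float:
    """Accuracy as a +/- half-range from a full-range maximum error ratio."""
    if full_range_error_pct < 0:
        raise DomainError(f"error must be >= 0, got {full_range_error_pct!r}")
    return full_range_error_pct / 2.0


def env_error_bounds(
    v_low: float, v_high: float, spec: SensorSpec = SensorSpec()
) -> EnvErrorBounds:
    """Water-content error interval for an output-voltage fluctuation interval.

    Each voltage bound is converted through the rounded sensitivity factor
    and rounded to two decimals; the half-width is half the *unrounded*
    converted interval width, rounded to three decimals (the convention that
    reproduces the characterized +/-0.635 % figure).
    """
    if v_low < 0 or v_low > v_high:
        raise DomainError(f"need 0 <= v_low <= v_high, got ({v_low!r}, {v_high!r})")
    factor = sensitivity_factor(spec).rounded
    low = round(v_low * factor, 2)
    high = round(v_high * factor, 2)
    half_width = round((v_high - v_low) * factor / 2.0, 3)
    return EnvErrorBounds(low=low, high=high, half_width=half_width)


def energy_index(inputs: EnergyIndexInputs) -> float:
    """Radial energy index Kw (%): ``(Uc - Ux) / (Uc - U0) * 100``.

    100 % at the air reference, 0 % at the water reference (saturation).
    Values outside [0, 100] are possible if ``Ux`` drifts outside the two
    references; they are flagged with a warning, not clamped.
    """
    kw = (inputs.Uc - inputs.Ux) / (inputs.Uc - inputs.U0) * 100.0
    if not 0.0 <= kw <= 100.0:
        warnings.warn(
            f"energy index {kw:.2f}% lies outside [0, 100]%: test voltage is "
            "outside the air/water reference span",
            CharacterizationWarning,
            stacklevel=2,
        )
    return kw


def conductivity_delta(Un_prime: float, U0_prime: float) -> float:
    """Signed output change (V) relative to the first conductivity gradient."""
    return Un_prime - U0_prime


def coverage_area(geom: ElectrodeGeometry) -> float:
    """Electrode surface coverage area (mm^2): ``2 * pi * ring_dim * width``.

    The printed ring dimension is plugged in directly (the characterized
    10-40 mm figures follow from exactly this usage).
    """
    return 2.0 * geom.pi_value * geom.ring_dim_mm * geom.width_mm


def characterization_report(
    spec: SensorSpec = SensorSpec(),
    full_range_error_pct: float = 3.52,
    env_v_low: float = 0.005,
    env_v_high: float = 0.025,
    coverage_pi: float = 3.14,
) -> dict:
    """Full characterization report as a plain dict (JSON-serializable)."""
    sens = sensitivity_factor(spec)
    env = env_error_bounds(env_v_low, env_v_high, spec)
    coverage = {
        f"{d} mm": coverage_area(
            ElectrodeGeometry(ring_dim_mm=d, pi_value=coverage_pi)
        )
        for d in (10, 20, 30, 40)
    }
    return {
        "sensitivity_pct_per_v": sens.rounded,
        "sensitivity_pct_per_v_raw": sens.raw,
        "resolution_pct": resolution(spec),
        "accuracy_pm_pct": accuracy_pm(full_range_error_pct),
        "env_error_low_pct": env.low,
        "env_error_high_pct": env.high,
        "env_error_pm_pct": env.half_width,
        "coverage_area_mm2": coverage,
    }
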