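"""Synthetic-experiment generator.

Stands in for the hardware: builds chamber/field temperature protocols,
drives a first-order liquid<->ice phase-relaxation model with known ground
truth, and synthesizes noisy sensor voltages either by inverting the
calibration line (default) or through the full probe-physics forward chain.

The phase dynamics are a fixture generator, not a scientific claim: the
frozen fraction relaxes exponentially toward a temperature-dependent
equilibrium (fully liquid above the freezing point, all-but-a-residual
frozen below it).
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .calibration import CalibrationModel
from .core_model import (
    DEFAULT_MIXTURE_RESISTANCE,
    PhaseComposition,
    ProbePhysics,
    mixture_impedance,
    probe_voltage,
)
from .errors import DomainError
from .freeze_thaw import SensorReading

#: Default simulation start instant (arbitrary mid-winter epoch).
DEFAULT_START = _dt.datetime(2019, 1, 1, 0, 0, 0, tzinfo=_dt.timezone.utc)


@dataclass(frozen=True)
class TemperatureProtocol:
    """A chamber ramp cycle or a sinusoidal diurnal field protocol.

    ``ramp_cycle``: staircase from ``start_c`` down to ``min_c`` in steps of
    ``step_c`` every ``step_minutes``, then back up — the chamber freeze–thaw
    drill.  ``diurnal``: sinusoid of given mean/amplitude/period sampled for
    ``duration_days``.
    """

    kind: Literal["ramp_cycle", "diurnal"]
    start_c: float = 20.0
    min_c: float = -16.0
    step_c: float = 3.0
    step_minutes: float = 10.0
    mean_c: float = -5.0
    amplitude_c: float = 10.0
    period_hours: float = 24.0
    duration_days: float = 3.0

    def __post_init__(self) -> None:
        if self.kind not in ("ramp_cycle", "diurnal"):
            raise DomainError(f"unknown protocol kind {self.kind!r}")
        if self.kind == "ramp_cycle":
            if not self.min_c < self.start_c:
                raise DomainError("ramp_cycle needs min_c < start_c")
            if not self.step_c > 0:
                raise DomainError("step_c must be > 0")
        if not self.step_minutes > 0:
            raise DomainError("step_minutes must be > 0")


#: Chamber drill on simulated branches: 20 -> -16 -> 20 C at 3 C per 10 min.
CHAMBER_A = TemperatureProtocol(kind="ramp_cycle", start_c=20.0, min_c=-16.0,
                                step_c=3.0, step_minutes=10.0)
#: Chamber drill on live branches: 20 -> -20 -> 20 C at 2 C per 10 min.
CHAMBER_B = TemperatureProtocol(kind="ramp_cycle", start_c=20.0, min_c=-20.0,
                                step_c=2.0, step_minutes=10.0)


@dataclass(frozen=True)
class PhaseDynamicsParams:
    """First-order liquid<->ice relaxation parameters."""

    theta_total: float = 45.0  # total volumetric water content, %
    freeze_point_c: float = 0.0
    rate_per_min: float = 0.5  # relaxation rate toward equilibrium, 1/min
    unfrozen_fraction_min: float = 0.05  # residual liquid fraction at deep frost

    def __post_init__(self) -> None:
        if not 0.0 < self.theta_total <= 100.0:
            raise DomainError("theta_total must be in (0, 100] %")
        if not self.rate_per_min > 0:
            raise DomainError("rate_per_min must be > 0")
        if not 0.0 <= self.unfrozen_fraction_min < 1.0:
            raise DomainError("unfrozen_fraction_min must be in [0, 1)")


@dataclass(frozen=True)
class SimulationConfig:
    """Everything needed for one reproducible synthetic run."""

    protocol: TemperatureProtocol = CHAMBER_A
    dynamics: PhaseDynamicsParams = PhaseDynamicsParams()
    noise_sd_v: float = 0.002
    sample_minutes: float = 1.0  # 1 min indoors, 10 min field cadence
    seed: int = 0
    density_ratio: float = 0.917

    def __post_init__(self) -> None:
        if self.noise_sd_v < 0:
            raise DomainError("noise_sd_v must be >= 0")
        if not self.sample_minutes > 0:
            raise DomainError("sample_minutes must be > 0")


@dataclass(frozen=True)
class GroundTruth:
    """Per-sample simulator ground truth (parallel arrays)."""

    minutes: np.ndarray
    temp_c: np.ndarray
    theta_liquid: np.ndarray  # %
    delta_true: np.ndarray  # %


def make_temperature_series(
    protocol: TemperatureProtocol, sample_minutes: float = 1.0
) -> tuple[np.ndarray, np.ndarray]:
    """Sampled temperature series for a protocol.

    Returns (minutes since start, temperature in C).  A ramp cycle is a
    piecewise-constant staircase down then back up; a diurnal protocol is a
    sinusoid at the sampling cadence.
    """
    if not sample_minutes > 0:
        raise DomainError("sample_minutes must be > 0")
    if protocol.kind == "ramp_cycle":
        n_down = int(np.ceil((protocol.start_c - protocol.min_c) / protocol.step_c))
        down = protocol.start_c - protocol.step_c * np.arange(n_down + 1)
        down = np.maximum(down, protocol.min_c)
        levels = np.concatenate([down, down[-2::-1]])
        total = len(levels) * protocol.step_minutes
        minutes = np.arange(0.0, total, sample_minutes)
        idx = np.minimum((minutes // protocol.step_minutes).astype(int), len(levels) - 1)
        return minutes, levels[idx]
    total = protocol.duration_days * 24.0 * 60.0
    minutes = np.arange(0.0, total, sample_minutes)
    phase = 2.0 * np.pi * minutes / (protocol.period_hours * 60.0)
    return minutes, protocol.mean_c + protocol.amplitude_c * np.sin(phase)


def simulate_phase(
    temps: np.ndarray,
    dynamics: PhaseDynamicsParams,
    sample_minutes: float = 1.0,
    density_ratio: float = 0.917,
) -> tuple[np.ndarray, np.ndarray]:
    """Liquid water content and true ice content along a temperature series.

    The frozen fraction ``f`` relaxes each sample toward its equilibrium —
    0 above the freezing point, ``1 - unfrozen_fraction_min`` at or below
    it — with per-sample factor ``exp(-rate_per_min * sample_minutes)``.
    Mass is conserved: ``theta_liquid + delta_true / density_ratio`` equals
    ``theta_total`` at every sample.
    """
    temps = np.asarray(temps, dtype=float)
    decay = float(np.exp(-dynamics.rate_per_min * sample_minutes))
    f_eq = np.where(temps <= dynamics.freeze_point_c,
                    1.0 - dynamics.unfrozen_fraction_min, 0.0)
    f = np.empty_like(temps)
    prev = 0.0
    for i in range(len(temps)):
        prev = f_eq[i] + (prev - f_eq[i]) * decay
        f[i] = prev
    theta_liquid = dynamics.theta_total * (1.0 - f)
    delta_true = (dynamics.theta_total - theta_liquid) * density_ratio
    return theta_liquid, delta_true


def simulate_readings(
    config: SimulationConfig,
    calibration: CalibrationModel,
    mode: Literal["calibration", "physics"] = "calibration",
    physics: ProbePhysics | None = None,
    mixture_resistance: float = DEFAULT_MIXTURE_RESISTANCE,
    start: _dt.datetime = DEFAULT_START,
) -> tuple[list[SensorReading], GroundTruth]:
    """Noisy sensor readings plus ground truth for one synthetic run.

    ``calibration`` mode inverts the calibration line
    (``U = (theta_liquid - b) / k``), decoupling pipeline tests from the
    probe-physics modelling choices; ``physics`` mode routes the liquid
    volume fraction through the mixture-impedance / reflection-voltage
    forward chain instead.  Gaussian voltage noise is seeded from
    ``config.seed``; output is byte-deterministic for a fixed config.
    """
    if calibration.slope_k == 0:
        raise DomainError("calibration slope must be nonzero to synthesize voltages")
    minutes, temps = make_temperature_series(config.protocol, config.sample_minutes)
    theta_liquid, delta_true = simulate_phase(
        temps, config.dynamics, config.sample_minutes, config.density_ratio
    )
    if mode == "calibration":
        clean = (theta_liquid - calibration.intercept_b) / calibration.slope_k
    elif mode == "physics":
        phys = physics or ProbePhysics()
        clean = np.empty_like(theta_liquid)
        for i, theta in enumerate(theta_liquid):
            comp = PhaseComposition(V=1.0, Vl=theta / 100.0)
            zp = mixture_impedance(comp, mixture_resistance, phys, mode="simplified")
            clean[i] = probe_voltage(zp, phys)
    else:
        raise DomainError(f"unknown simulation mode {mode!r}")
    rng = np.random.default_rng(config.seed)
    U = clean + rng.normal(0.0, config.noise_sd_v, size=clean.shape)
    readings = [
        SensorReading(
            timestamp=start + _dt.timedelta(minutes=float(m)),
            U=float(u),
            temp=float(t),
        )
        for m, u, t in zip(minutes, U, temps)
    ]
    truth = GroundTruth(minutes=minutes, temp_c=temps,
                        theta_liquid=theta_liquid, delta_true=delta_true)
    return readings, truth
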