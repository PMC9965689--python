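"""Forward physics of the impedance probe.

The branch is modelled as a three-phase (gas/liquid/solid) dielectric mixture
sitting between the ring electrodes of a coaxial probe.  The total impedance
is a parallel resistance plus an imaginary term proportional to the angular
frequency and the volume-weighted phase permittivities; the probe electronics
turn the reflection at the line/probe interface into an amplified DC voltage.

Conventions
-----------
* The imaginary impedance term is ``w * (sum of capacitances)`` — the printed
  form of the source model — not the ``1/(w*C)`` of a textbook RC parallel
  network.  Only the monotone liquid-water -> impedance -> voltage mapping is
  required, and this form provides it.
* The probe output voltage is the signed real projection of the complex
  reflection expression ``2 * beta0 * A * (ZP - ZL) / (ZP + ZL)``, modelling
  the rectified/amplified analog level the hardware emits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .errors import DomainError, NoPassiveSolutionError, SingularityError

#: Vacuum permittivity used throughout (F/m).
VACUUM_PERMITTIVITY = 8.85e-12

#: Default operating angular frequency: 100 MHz excitation.
DEFAULT_ANGULAR_FREQUENCY = 2.0 * math.pi * 1.0e8

#: Default mixture resistance used by the physics-mode simulator (ohm); the
#: resistive component of branch tissue stays in the 0-20 ohm band at 100 MHz.
DEFAULT_MIXTURE_RESISTANCE = 10.0

#: Default amplification.  With A = 1 V, k_geo = 1 mm, R = 10 ohm and a
#: 100 MHz excitation, a full 0 -> 100 % liquid-water sweep then spans
#: ~1.574 V of output, matching the characterized full-scale span.  The
#: reflection change of the as-printed impedance model is minuscule at these
#: scales, so the lumped gain absorbs everything the real front end does.
DEFAULT_BETA0 = 8.3794e9


@dataclass(frozen=True)
class EquivalentCircuit:
    """Parallel RC equivalent circuit of the three phases.

    Parameters
    ----------
    Rg, Rl, Rs : float
        Resistance (ohm) of the gas, liquid and solid phases; all > 0.
    Cg, Cl, Cs : float
        Capacitance (F) of the gas, liquid and solid phases; all >= 0.
    """

    Rg: float
    Rl: float
    Rs: float
    Cg: float = 0.0
    Cl: float = 0.0
    Cs: float = 0.0

    def __post_init__(self) -> None:
        for name in ("Rg", "Rl", "Rs"):
            if not getattr(self, name) > 0:
                raise DomainError(f"{name} must be > 0, got {getattr(self, name)!r}")
        for name in ("Cg", "Cl", "Cs"):
            if getattr(self, name) < 0:
                raise DomainError(f"{name} must be >= 0, got {getattr(self, name)!r}")


@dataclass(frozen=True)
class PhaseComposition:
    """Volumetric three-phase composition of a branch segment.

    Volumes are in m^3 (any consistent unit works — only ratios enter the
    model); permittivities are relative (dimensionless).
    """

    V: float
    Vl: float
    Vg: float = 0.0
    Vs: float = 0.0
    eps_g: float = 1.0
    eps_l: float = 81.0
    eps_s: float = 3.0

    def __post_init__(self) -> None:
        if not self.V > 0:
            raise DomainError(f"total volume must be > 0, got {self.V!r}")
        for name in ("Vg", "Vl", "Vs"):
            if getattr(self, name) < 0:
                raise DomainError(f"{name} must be >= 0")
        if self.Vg + self.Vl + self.Vs > self.V * (1 + 1e-12):
            raise DomainError("phase volumes exceed the total branch volume")
        if self.eps_g < 1 or self.eps_l < 1 or self.eps_s < 1:
            raise DomainError("relative permittivities must be >= 1")


@dataclass(frozen=True)
class ProbePhysics:
    """Probe/circuit constants.

    Parameters
    ----------
    k_geo : float
        Electrode geometry factor (m).  Never published for this probe;
        1e-3 m is an arbitrary, documented default.
    w : float
        Angular excitation frequency (rad/s); default 2*pi*100 MHz.
    ZL : float
        Coaxial transmission-line impedance (ohm); default 50.
    beta0 : float
        Amplification of the difference amplifier (dimensionless).
    A : float
        Excitation source amplitude (V).
    eps0 : float
        Vacuum permittivity (F/m); fixed at 8.85e-12.
    """

    k_geo: float = 1.0e-3
    w: float = DEFAULT_ANGULAR_FREQUENCY
    ZL: float = 50.0
    beta0: float = DEFAULT_BETA0
    A: float = 1.0
    eps0: float = field(default=VACUUM_PERMITTIVITY)

    def __post_init__(self) -> None:
        for name in ("k_geo", "w", "ZL", "beta0", "A", "eps0"):
            if not getattr(self, name) > 0:
                raise DomainError(f"{name} must be > 0, got {getattr(self, name)!r}")

    @property
    def full_scale(self) -> float:
        """Maximum output magnitude ``2 * beta0 * A`` (V, total reflection)."""
        return 2.0 * self.beta0 * self.A


@dataclass(frozen=True)
class ComplexImpedance:
    """Impedance split into resistance (real) and reactance (imaginary), ohm."""

    resistance: float
    reactance: float = 0.0

    def __post_init__(self) -> None:
        if self.resistance < 0:
            raise DomainError(
                f"resistance must be >= 0 for a physical branch, got {self.resistance!r}"
            )

    @property
    def as_complex(self) -> complex:
        return complex(self.resistance, self.reactance)


def parallel_resistance(circuit: EquivalentCircuit) -> float:
    """Total parallel resistance ``Rg // Rl // Rs`` (ohm).

    Always strictly below the smallest of the three branch resistances.
    """
    return 1.0 / (1.0 / circuit.Rg + 1.0 / circuit.Rl + 1.0 / circuit.Rs)


def circuit_impedance(circuit: EquivalentCircuit, physics: ProbePhysics) -> ComplexImpedance:
    """Total impedance of the three-phase equivalent circuit.

    Real part is the parallel resistance; imaginary part is
    ``w * (Cg + Cl + Cs)`` exactly as the model is written.
    """
    return ComplexImpedance(
        resistance=parallel_resistance(circuit),
        reactance=physics.w * (circuit.Cg + circuit.Cl + circuit.Cs),
    )


def permittivity_from_capacitance(C: float, physics: ProbePhysics) -> float:
    """Relative permittivity of a capacitance ``C`` for this electrode geometry."""
    if C < 0:
        raise DomainError(f"capacitance must be >= 0, got {C!r}")
    return C / (physics.k_geo * physics.eps0)


def capacitance_from_permittivity(eps_r: float, physics: ProbePhysics) -> float:
    """Inverse of :func:`permittivity_from_capacitance`."""
    if eps_r < 0:
        raise DomainError(f"relative permittivity must be >= 0, got {eps_r!r}")
    return eps_r * physics.k_geo * physics.eps0


def mixture_impedance(
    comp: PhaseComposition,
    R_total: float,
    physics: ProbePhysics,
    mode: str = "full",
) -> ComplexImpedance:
    """Impedance of the dielectric mixture at the probe.

    ``mode="full"`` weighs all three phase permittivities by their volume
    fractions; ``mode="simplified"`` keeps only the liquid term, which
    dominates because water's permittivity (~81) dwarfs the gas (~1) and
    solid/ice (~3) contributions.  The imaginary part is strictly increasing
    in the liquid volume, which is the physical basis of the measurement.
    """
    if not R_total > 0:
        raise DomainError(f"R_total must be > 0, got {R_total!r}")
    if mode not in ("full", "simplified"):
        raise DomainError(f"unknown mixture mode {mode!r}")
    scale = physics.w * physics.k_geo * physics.eps0
    liquid = comp.eps_l * comp.Vl / comp.V
    if mode == "full":
        weighted = comp.eps_g * comp.Vg / comp.V + liquid + comp.eps_s * comp.Vs / comp.V
    else:
        weighted = liquid
    return ComplexImpedance(resistance=R_total, reactance=scale * weighted)


def probe_voltage(ZP: ComplexImpedance | complex, physics: ProbePhysics) -> float:
    """Amplified output voltage for a probe impedance ``ZP``.

    ``U = 2 * beta0 * A * Re[(ZP - ZL)/(ZP + ZL)]``; zero for a matched load
    and bounded by ``2 * beta0 * A`` in magnitude for any passive load.
    """
    z = ZP.as_complex if isinstance(ZP, ComplexImpedance) else complex(ZP)
    denom = z + physics.ZL
    if abs(denom) == 0.0:
        raise SingularityError("ZP == -ZL: reflection expression is singular")
    gamma = (z - physics.ZL) / denom
    return 2.0 * physics.beta0 * physics.A * gamma.real


def impedance_from_voltage(U: float, physics: ProbePhysics) -> ComplexImpedance:
    """Purely resistive load producing output voltage ``U``.

    Exists only for ``|U| < 2 * beta0 * A`` (passive loads); inverse of
    :func:`probe_voltage` restricted to the real axis.
    """
    full = physics.full_scale
    if abs(U) >= full:
        raise NoPassiveSolutionError(
            f"|U| = {abs(U)!r} V is at or beyond the passive limit {full!r} V"
        )
    gamma = U / full
    resistance = physics.ZL * (1.0 + gamma) / (1.0 - gamma)
    return ComplexImpedance(resistance=resistance, reactance=0.0)
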