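"""Dimensionless-number screening that justifies the modelling assumptions.

Three gates must hold for the model to be self-consistent:

* ``Re_f = 4 rho_f omega R_i^2 / mu_f < 2000`` — laminar flow, so the
  steady incompressible Stokes equations describe the stirred well;
* ``Stk = t0 vt / (2 R_p) < 1`` — microtissues respond much faster than
  the flow changes along their path and behave as stream tracers, which
  justifies one-way flow-to-particle coupling;
* ``Re_p = 2 rho_p vt R_p / mu_f < 1`` — the slip Reynolds number is small,
  so the analytic Stokes drag law applies.

Here ``t0 = rho_p (2 R_p)^2 / (18 mu_f)`` is the particle response time and
``vt = 2 (rho_p - rho_f) g R_p^2 / (9 mu_f)`` the Stokes terminal settling
velocity. Note that ``Re_p`` is defined with the particle density rho_p
(rather than the conventional fluid density); the two differ by at most a
few percent at the relative excess densities considered here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .config import FluidProperties, ParticleSpec, ProcessConfig
from .exceptions import InvalidParameterError

__all__ = [
    "fluid_reynolds",
    "settling_velocity",
    "response_time",
    "stokes_number",
    "particle_reynolds",
    "regime_report",
    "DimensionlessReport",
    "LAMINAR_THRESHOLD",
]

#: Laminar gate on the fluid Reynolds number.
LAMINAR_THRESHOLD = 2000.0


def _check(name, value):
    if not math.isfinite(value) or value < 0:
        raise InvalidParameterError(f"{name} must be finite and >= 0, got {value!r}")
    return float(value)


def fluid_reynolds(fluid: FluidProperties, omega: float, radius: float) -> float:
    """Fluid Reynolds number Re_f = 4 rho_f omega R_i^2 / mu_f."""
    omega = _check("omega", omega)
    radius = _check("impeller radius", radius)
    return 4.0 * fluid.density * omega * radius ** 2 / fluid.viscosity


def settling_velocity(p: ParticleSpec, fluid: FluidProperties) -> float:
    """Stokes terminal velocity vt = 2 (rho_p - rho_f) g R_p^2 / (9 mu_f).

    Positive values sink; negative values rise (rho_p < rho_f).
    """
    return (2.0 * (p.density - fluid.density) * fluid.gravity * p.radius ** 2
            / (9.0 * fluid.viscosity))


def response_time(p: ParticleSpec, fluid: FluidProperties) -> float:
    """Particle response time t0 = rho_p (2 R_p)^2 / (18 mu_f)."""
    return p.density * (2.0 * p.radius) ** 2 / (18.0 * fluid.viscosity)


def stokes_number(p: ParticleSpec, fluid: FluidProperties) -> float:
    """Stk = t0 |vt| / (2 R_p)."""
    if p.radius <= 0:
        raise InvalidParameterError("particle radius must be > 0")
    return (response_time(p, fluid) * abs(settling_velocity(p, fluid))
            / (2.0 * p.radius))


def particle_reynolds(p: ParticleSpec, fluid: FluidProperties) -> float:
    """Re_p = 2 rho_p |vt| R_p / mu_f (rho_p as conventionally printed here)."""
    return (2.0 * p.density * abs(settling_velocity(p, fluid)) * p.radius
            / fluid.viscosity)


@dataclass(frozen=True)
class DimensionlessReport:
    """All screening numbers plus the pass/fail flags for the three gates."""

    fluid_reynolds: float
    response_time: float       # t0, s
    terminal_velocity: float   # vt, m/s (signed)
    stokes_number: float
    particle_reynolds: float

    @property
    def laminar_ok(self) -> bool:
        return self.fluid_reynolds < LAMINAR_THRESHOLD

    @property
    def tracer_ok(self) -> bool:
        return self.stokes_number < 1.0

    @property
    def stokes_drag_ok(self) -> bool:
        return self.particle_reynolds < 1.0

    @property
    def all_ok(self) -> bool:
        return self.laminar_ok and self.tracer_ok and self.stokes_drag_ok

    def as_table(self) -> str:
        rows = [
            ("Re_f (fluid Reynolds)", f"{self.fluid_reynolds:.4g}"),
            ("  laminar (Re_f < 2000)", "PASS" if self.laminar_ok else "FAIL"),
            ("t0 (response time, s)", f"{self.response_time:.4g}"),
            ("vt (terminal velocity, m/s)", f"{self.terminal_velocity:.4g}"),
            ("Stk (Stokes number)", f"{self.stokes_number:.4g}"),
            ("  tracer (Stk < 1)", "PASS" if self.tracer_ok else "FAIL"),
            ("Re_p (particle Reynolds)", f"{self.particle_reynolds:.4g}"),
            ("  Stokes drag (Re_p < 1)", "PASS" if self.stokes_drag_ok else "FAIL"),
        ]
        width = max(len(k) for k, _ in rows)
        return "\n".join(f"{k:<{width}}  {v}" for k, v in rows)


def regime_report(cfg: ProcessConfig) -> DimensionlessReport:
    """Evaluate all dimensionless gates for a process configuration."""
    return DimensionlessReport(
        fluid_reynolds=fluid_reynolds(cfg.fluid,
                                      cfg.impeller.angular_velocity,
                                      cfg.impeller.radius),
        response_time=response_time(cfg.particle, cfg.fluid),
        terminal_velocity=settling_velocity(cfg.particle, cfg.fluid),
        stokes_number=stokes_number(cfg.particle, cfg.fluid),
        particle_reynolds=particle_reynolds(cfg.particle, cfg.fluid),
    )
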