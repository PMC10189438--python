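"""Process configuration for the 2-ml mini stirred-tank bioreactor (miniBR).

A single well of a 24-well plate holds 2 ml of culture medium stirred by a
small impeller run at 7, 13 or 20 rad/s (low / medium / high regime). The
microtissue population is modelled as soft spheres a bit denser than the
medium. Every physical default below is the single source of truth for a
simulation and can be overridden from a YAML config file.

Default rationale (no vessel/fluid constants are tabulated for this system,
so the package fixes field-standard values once):

* fluid: water-like chondrogenic medium at 37 C, rho_f = 993 kg/m^3,
  mu_f = 7.0e-4 Pa s;
* vessel: standard 24-well, R_w = 7.8 mm, liquid height from the 2-ml
  working volume (H ~ 10.5 mm);
* impeller: R_i = 4 mm, the largest centimetre-scale radius that keeps the
  fluid Reynolds number below the laminar threshold at 20 rad/s, hub
  clearance 5 mm (blades near mid-height, as for a shaft-suspended marine
  impeller; this placement also reproduces the observed low-shear zone
  beneath / high-shear zone above the impeller), actuator half-thickness
  1 mm, 30 deg pitch, pumping number N_q = 0.4 (typical marine impeller);
* particle: radius 60 um (120 um diameter inoculum), relative excess
  density delta = 0.05 (mid-high value of the 0-0.06 sweep range, so
  gravitational settling is visible).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Optional

import yaml

from .exceptions import InvalidParameterError

__all__ = [
    "FluidProperties",
    "ImpellerSpec",
    "VesselGeometry",
    "ParticleSpec",
    "ProcessConfig",
    "REGIME_SPEEDS",
    "default_config",
    "load_config",
    "save_config",
    "cells_per_microtissue",
]

#: Impeller speeds (rad/s) of the three culture regimes.
REGIME_SPEEDS = {"low": 7.0, "medium": 13.0, "high": 20.0}


def _require_finite(name: str, value: float, positive: bool = False,
                    nonnegative: bool = False) -> float:
    value = float(value)
    if not math.isfinite(value):
        raise InvalidParameterError(f"{name} must be finite, got {value!r}")
    if positive and value <= 0:
        raise InvalidParameterError(f"{name} must be > 0, got {value!r}")
    if nonnegative and value < 0:
        raise InvalidParameterError(f"{name} must be >= 0, got {value!r}")
    return value


@dataclass(frozen=True)
class FluidProperties:
    """Newtonian culture medium. SI units throughout."""

    density: float = 993.0          # rho_f, kg/m^3
    viscosity: float = 7.0e-4       # mu_f, Pa s
    gravity: float = 9.81           # g, m/s^2

    def __post_init__(self):
        _require_finite("fluid density", self.density, positive=True)
        _require_finite("fluid viscosity", self.viscosity, positive=True)
        _require_finite("gravity", self.gravity, nonnegative=True)

    @property
    def kinematic_viscosity(self) -> float:
        """nu = mu_f / rho_f (m^2/s)."""
        return self.viscosity / self.density


@dataclass(frozen=True)
class VesselGeometry:
    """One cylindrical well; flat free surface at z = height."""

    radius: float = 7.8e-3          # R_w, m
    height: float = 2.0e-6 / (math.pi * 7.8e-3 ** 2)  # H from 2-ml volume, m

    def __post_init__(self):
        _require_finite("well radius", self.radius, positive=True)
        _require_finite("liquid height", self.height, positive=True)

    @property
    def volume(self) -> float:
        """Working volume pi R_w^2 H (m^3)."""
        return math.pi * self.radius ** 2 * self.height

    @classmethod
    def from_volume(cls, radius: float = 7.8e-3,
                    volume: float = 2.0e-6) -> "VesselGeometry":
        return cls(radius=radius, height=volume / (math.pi * radius ** 2))


@dataclass(frozen=True)
class ImpellerSpec:
    """Impeller reduced to an actuator annulus in the axisymmetric model.

    The annulus spans radii [hub_radius, radius] and heights
    [clearance, clearance + 2 * half_thickness]; the classifier's
    "impeller plane" is z = clearance.
    """

    radius: float = 4.0e-3            # R_i, m
    angular_velocity: float = 13.0    # omega, rad/s
    clearance: float = 5.0e-3         # hub clearance above vessel bottom, m
    half_thickness: float = 1.0e-3    # actuator axial half-thickness, m
    pitch: float = math.radians(30.0)  # blade pitch angle, rad
    pumping_number: float = 0.4       # N_q, dimensionless
    hub_radius: float = 1.0e-3        # inner radius of the actuator annulus, m

    def __post_init__(self):
        _require_finite("impeller radius", self.radius, positive=True)
        _require_finite("angular velocity", self.angular_velocity,
                        nonnegative=True)
        _require_finite("clearance", self.clearance, nonnegative=True)
        _require_finite("half thickness", self.half_thickness, positive=True)
        _require_finite("pumping number", self.pumping_number, nonnegative=True)
        _require_finite("hub radius", self.hub_radius, nonnegative=True)
        if not self.hub_radius < self.radius:
            raise InvalidParameterError("hub radius must be < impeller radius")

    @property
    def tip_speed(self) -> float:
        """omega * R_i (m/s)."""
        return self.angular_velocity * self.radius

    @property
    def target_flow(self) -> float:
        """Actuator throughput Q = N_q * omega * R_i^3 (m^3/s, upward)."""
        return self.pumping_number * self.angular_velocity * self.radius ** 3

    def validate_against(self, geom: VesselGeometry) -> None:
        if not self.radius < geom.radius:
            raise InvalidParameterError("impeller radius must be < well radius")
        if not self.clearance + 2 * self.half_thickness < geom.height:
            raise InvalidParameterError(
                "actuator must lie below the free surface")


@dataclass(frozen=True)
class ParticleSpec:
    """One microtissue treated as a soft sphere."""

    radius: float = 60.0e-6           # R_p, m
    density: float = 993.0 * 1.05     # rho_p, kg/m^3

    def __post_init__(self):
        _require_finite("particle radius", self.radius, positive=True)
        _require_finite("particle density", self.density, positive=True)

    def relative_excess_density(self, fluid: FluidProperties) -> float:
        """delta = (rho_p - rho_f) / rho_f."""
        return (self.density - fluid.density) / fluid.density

    @classmethod
    def from_delta(cls, delta: float, fluid: FluidProperties = FluidProperties(),
                   radius: float = 60.0e-6) -> "ParticleSpec":
        return cls(radius=radius, density=fluid.density * (1.0 + delta))

    @property
    def volume(self) -> float:
        return 4.0 / 3.0 * math.pi * self.radius ** 3

    @property
    def mass(self) -> float:
        return self.density * self.volume


@dataclass(frozen=True)
class ContactParams:
    """Linear spring-dashpot normal contact (pair and wall)."""

    normal_stiffness: float = 1.0e-2   # k_n, N/m
    damping_ratio: float = 0.1         # dimensionless, restitution-equivalent
    wall_stiffness: float = 1.0e-2     # N/m

    def __post_init__(self):
        _require_finite("normal stiffness", self.normal_stiffness,
                        nonnegative=True)
        _require_finite("damping ratio", self.damping_ratio, nonnegative=True)
        _require_finite("wall stiffness", self.wall_stiffness,
                        nonnegative=True)


@dataclass(frozen=True)
class ProcessConfig:
    """Everything a simulation run needs, in SI units."""

    fluid: FluidProperties = field(default_factory=FluidProperties)
    vessel: VesselGeometry = field(default_factory=VesselGeometry)
    impeller: ImpellerSpec = field(default_factory=ImpellerSpec)
    particle: ParticleSpec = field(default_factory=ParticleSpec)
    contact: ContactParams = field(default_factory=ContactParams)
    n_particles: int = 2000           # microtissues per well
    seed: int = 0
    duration: float = 60.0            # simulated time, s
    dt: Optional[float] = None        # None -> automatic stability bound
    grid: tuple = (64, 96)            # (nr, nz) flow-grid nodes
    sample_every: int = 10            # trajectory cadence, steps
    regime: Optional[str] = None      # low | medium | high

    def __post_init__(self):
        if self.n_particles < 1:
            raise InvalidParameterError("n_particles must be >= 1")
        _require_finite("duration", self.duration, nonnegative=True)
        if self.dt is not None:
            _require_finite("dt", self.dt, positive=True)
        if self.sample_every < 1:
            raise InvalidParameterError("sample_every must be >= 1")
        nr, nz = self.grid
        if nr < 8 or nz < 8:
            raise InvalidParameterError("grid must be at least 8x8")
        if self.regime is not None:
            if self.regime not in REGIME_SPEEDS:
                raise InvalidParameterError(
                    f"unknown regime {self.regime!r}; "
                    f"expected one of {sorted(REGIME_SPEEDS)}")
            omega = REGIME_SPEEDS[self.regime]
            if not math.isclose(self.impeller.angular_velocity, omega):
                raise InvalidParameterError(
                    f"regime {self.regime!r} implies omega = {omega} rad/s, "
                    f"got {self.impeller.angular_velocity}")
        self.impeller.validate_against(self.vessel)

    def with_regime(self, regime: str) -> "ProcessConfig":
        """Return a copy with the impeller speed of the named regime."""
        if regime not in REGIME_SPEEDS:
            raise InvalidParameterError(f"unknown regime {regime!r}")
        imp = replace(self.impeller, angular_velocity=REGIME_SPEEDS[regime])
        return replace(self, impeller=imp, regime=regime)

    def with_delta(self, delta: float) -> "ProcessConfig":
        """Return a copy with particle density rho_f * (1 + delta)."""
        part = ParticleSpec.from_delta(delta, self.fluid,
                                       radius=self.particle.radius)
        return replace(self, particle=part)


def default_config(regime: str = "medium", **overrides) -> ProcessConfig:
    return ProcessConfig().with_regime(regime) if not overrides else \
        replace(ProcessConfig().with_regime(regime), **overrides)


# --------------------------------------------------------------------------
# YAML round trip

def _to_dict(cfg: ProcessConfig) -> dict:
    d = asdict(cfg)
    d["grid"] = list(cfg.grid)
    return d


def save_config(cfg: ProcessConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(_to_dict(cfg), sort_keys=True))


def load_config(path) -> ProcessConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return config_from_dict(raw)


def config_from_dict(raw: dict) -> ProcessConfig:
    kwargs = dict(raw)
    sub = {
        "fluid": FluidProperties,
        "vessel": VesselGeometry,
        "impeller": ImpellerSpec,
        "particle": ParticleSpec,
        "contact": ContactParams,
    }
    for key, cls in sub.items():
        if key in kwargs and isinstance(kwargs[key], dict):
            kwargs[key] = cls(**kwargs[key])
    if "grid" in kwargs:
        kwargs["grid"] = tuple(kwargs["grid"])
    return ProcessConfig(**kwargs)


def cells_per_microtissue(cells_seeded: int = 500_000,
                          microwells: int = 2000) -> float:
    """Seeding arithmetic: cells seeded per well / microwells per well.

    With the defaults (500,000 human periosteum-derived cells over ~2000
    agarose microwells) each microtissue starts from ~250 cells.
    """
    if microwells < 1 or cells_seeded < 0:
        raise InvalidParameterError("need microwells >= 1, cells >= 0")
    return cells_seeded / microwells
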