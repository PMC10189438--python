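"""Center-based model of the microtissue suspension.

Each microtissue is a soft sphere advected one-way by the resolved flow.
Forces on a particle:

* Stokes drag ``6 pi mu_f R_p (u - v)`` (valid because Re_p < 1);
* the undisturbed-flow stress (pressure-gradient) force
  ``rho_f V Du/Dt`` — without it a neutrally buoyant particle in a swirling
  flow would spuriously centrifuge outward instead of tracing streamlines;
* Saffman shear-gradient lift in McLaughlin vector form with the Mei
  finite-Re correction (<= 1% of drag here; a sensitivity toggle exists);
* buoyant weight ``(rho_p - rho_f) V g`` downward;
* linear spring-dashpot normal contacts between particles and with walls.

Added-mass, Basset-history and Magnus forces are omitted: at Stk ~ 5e-3
they are negligible against drag. Integration is semi-implicit Euler with
the drag term implicit (the stiff term), time step bounded by t0/5 and by
a fifth of a grid-cell crossing at tip speed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from typing import List, Optional, Sequence

import numpy as np

from . import _kernels
from .config import (ContactParams, FluidProperties, ImpellerSpec,
                     ParticleSpec, ProcessConfig, VesselGeometry)
from .dimensionless import regime_report, response_time
from .exceptions import (IntegrityError, InvalidParameterError,
                         LaminarGateError, PackingError, TimeStepError)
from .flow import FlowField
from .sizes import SizeDistributionSpec, sample_steady_state, steady_state_spec

__all__ = [
    "ParticleState",
    "Trajectory",
    "Suspension",
    "init_population",
    "drag",
    "lift",
    "buoyant_weight",
    "contacts",
    "auto_dt",
    "simulate",
]


@dataclass
class ParticleState:
    """Kinematic state of one microtissue (SI, vessel-bottom-center origin,
    z up)."""

    id: int
    radius: float
    density: float
    position: np.ndarray
    velocity: np.ndarray

    def __post_init__(self):
        if self.radius <= 0 or self.density <= 0:
            raise InvalidParameterError("radius and density must be > 0")
        self.position = np.asarray(self.position, dtype=float).copy()
        self.velocity = np.asarray(self.velocity, dtype=float).copy()


@dataclass
class Trajectory:
    """Recorded path of one particle: equal-length sampled channels."""

    particle_id: int
    radius: float
    density: float
    t: np.ndarray            # (m,), strictly increasing, s
    position: np.ndarray     # (m, 3)
    velocity: np.ndarray     # (m, 3)
    fluid_velocity: np.ndarray  # (m, 3), local fluid velocity at samples

    def __post_init__(self):
        m = len(self.t)
        if not (self.position.shape == self.velocity.shape
                == self.fluid_velocity.shape == (m, 3)):
            raise InvalidParameterError("trajectory channels length mismatch")
        if m > 1 and not np.all(np.diff(self.t) > 0):
            raise InvalidParameterError("sample times must strictly increase")

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])


# --------------------------------------------------------------------------
# individual force laws (reference implementations; the numba kernel inlines
# the same math)

def drag(p: ParticleState, u_local, fluid: FluidProperties) -> np.ndarray:
    """Stokes drag F = 6 pi mu_f R_p (u - v) (N)."""
    u_local = np.asarray(u_local, dtype=float)
    return 6.0 * math.pi * fluid.viscosity * p.radius * (u_local - p.velocity)


def lift(p: ParticleState, u_local, vorticity, fluid: FluidProperties,
         mei_correction: bool = True) -> np.ndarray:
    """Saffman shear-gradient lift (N), McLaughlin vector form.

    F = 6.46 C mu_f R_p^2 (u - v) x omega_f / sqrt(nu |omega_f|), with
    omega_f = curl u the local fluid vorticity (the "velocity gradient"
    input reduced to its antisymmetric part) and C the Mei finite-Re_p
    correction. Zero when either the slip or the local shear vanishes;
    perpendicular to the slip by construction.
    """
    u_local = np.asarray(u_local, dtype=float)
    w = np.asarray(vorticity, dtype=float)
    slip = u_local - p.velocity
    wmag = float(np.linalg.norm(w))
    smag = float(np.linalg.norm(slip))
    if wmag < 1e-12 or smag < 1e-14:
        return np.zeros(3)
    nu = fluid.kinematic_viscosity
    c = 1.0
    if mei_correction:
        res = 2.0 * p.radius * smag * fluid.density / fluid.viscosity
        beta = min(p.radius * wmag / smag, 1.0)
        c = (1.0 - 0.3314 * math.sqrt(beta)) * math.exp(-res / 10.0) \
            + 0.3314 * math.sqrt(beta)
    coef = 6.46 * c * fluid.viscosity * p.radius ** 2 / math.sqrt(nu * wmag)
    return coef * np.cross(slip, w)


def buoyant_weight(p: ParticleState, fluid: FluidProperties) -> np.ndarray:
    """Net weight (rho_p - rho_f) V g, pointing down (N)."""
    v = 4.0 / 3.0 * math.pi * p.radius ** 3
    return np.array([0.0, 0.0, -(p.density - fluid.density) * v
                     * fluid.gravity])


def contacts(particles: Sequence[ParticleState], geom: VesselGeometry,
             params: Optional[ContactParams] = None) -> np.ndarray:
    """Per-particle contact force (n, 3) from pair and wall overlaps.

    Linear spring-dashpot, no tensile forces; Newton's third law holds
    pairwise by construction.
    """
    params = params or ContactParams()
    n = len(particles)
    forces = np.zeros((n, 3))
    kn, zeta, kw = (params.normal_stiffness, params.damping_ratio,
                    params.wall_stiffness)
    mass = [p.density * 4.0 / 3.0 * math.pi * p.radius ** 3 for p in particles]
    for a in range(n):
        for b in range(a + 1, n):
            dx = particles[a].position - particles[b].position
            dist = float(np.linalg.norm(dx))
            sumr = particles[a].radius + particles[b].radius
            if 0.0 < dist < sumr:
                nhat = dx / dist
                vreln = float((particles[a].velocity
                               - particles[b].velocity) @ nhat)
                meff = mass[a] * mass[b] / (mass[a] + mass[b])
                fmag = kn * (sumr - dist) \
                    - 2.0 * zeta * math.sqrt(kn * meff) * vreln
                if fmag > 0.0:
                    forces[a] += fmag * nhat
                    forces[b] -= fmag * nhat
    for a, p in enumerate(particles):
        x, y, z = p.position
        cw = 2.0 * zeta * math.sqrt(kw * mass[a])
        if z < p.radius:
            fmag = kw * (p.radius - z) - cw * p.velocity[2]
            if fmag > 0.0:
                forces[a, 2] += fmag
        if z > geom.height - p.radius:
            fmag = kw * (z - (geom.height - p.radius)) + cw * p.velocity[2]
            if fmag > 0.0:
                forces[a, 2] -= fmag
        r = math.hypot(x, y)
        if r > geom.radius - p.radius and r > 0.0:
            vr = (x * p.velocity[0] + y * p.velocity[1]) / r
            fmag = kw * (r - (geom.radius - p.radius)) + cw * vr
            if fmag > 0.0:
                forces[a, 0] -= fmag * x / r
                forces[a, 1] -= fmag * y / r
    return forces


# --------------------------------------------------------------------------
# population initialisation

def init_population(spec: SizeDistributionSpec, n: int, seed: int,
                    geom: VesselGeometry,
                    imp: Optional[ImpellerSpec] = None,
                    density: float = 993.0 * 1.05,
                    max_retries: int = 1000) -> List[ParticleState]:
    """Place ``n`` non-overlapping particles uniformly in the liquid volume.

    Radii are drawn from the (truncated) size distribution; positions are
    uniform in the cylinder, at least one radius away from every wall and
    outside the actuator annulus (if an impeller is given); initial
    velocity is zero. Reproducible for a fixed seed.
    """
    if n < 1:
        raise InvalidParameterError("n must be >= 1")
    rng = np.random.default_rng(seed)
    if spec.area_bounds is not None:
        radii = 0.5 * sample_steady_state(
            n, int(rng.integers(2 ** 31)), spec)
    else:
        sigma = spec.sigma_log
        radii = 0.5 * rng.lognormal(spec.mu_log, sigma, size=n)

    placed = np.empty((0, 3))
    particles: List[ParticleState] = []
    for k in range(n):
        rp = radii[k]
        ok = False
        for _ in range(max_retries):
            rpos = (geom.radius - rp) * math.sqrt(rng.uniform())
            theta = rng.uniform(0.0, 2.0 * math.pi)
            zpos = rng.uniform(rp, geom.height - rp)
            if imp is not None:
                in_r = imp.hub_radius - rp <= rpos <= imp.radius + rp
                in_z = (imp.clearance - rp <= zpos
                        <= imp.clearance + 2 * imp.half_thickness + rp)
                if in_r and in_z:
                    continue
            x = np.array([rpos * math.cos(theta), rpos * math.sin(theta),
                          zpos])
            if placed.size:
                d2 = np.sum((placed - x) ** 2, axis=1)
                if np.any(d2 < (radii[:k][: len(placed)] + rp) ** 2):
                    continue
            ok = True
            break
        if not ok:
            raise PackingError(
                f"could not place particle {k} after {max_retries} retries "
                f"(volume fraction too high); achieved n = {k}",
                achieved_n=k)
        placed = np.vstack([placed, x])
        particles.append(ParticleState(id=k, radius=rp, density=density,
                                       position=x, velocity=np.zeros(3)))
    return particles


def auto_dt(particles: Sequence[ParticleState], fluid: FluidProperties,
            field: Optional[FlowField] = None,
            imp: Optional[ImpellerSpec] = None) -> float:
    """Stability bound dt = min(t0_min / 5, 0.2 * cell / tip speed)."""
    t0_min = min(response_time(ParticleSpec(p.radius, p.density), fluid)
                 for p in particles)
    dt = t0_min / 5.0
    if field is not None and imp is not None and imp.tip_speed > 0:
        dt = min(dt, 0.2 * min(field.dr, field.dz) / imp.tip_speed)
    return dt


# --------------------------------------------------------------------------
# engine

class Suspension:
    """Array-backed particle ensemble advanced by the numba kernel."""

    def __init__(self, particles: Sequence[ParticleState],
                 fluid: FluidProperties, geom: VesselGeometry,
                 field: Optional[FlowField] = None,
                 contact: Optional[ContactParams] = None, *,
                 use_lift: bool = True, use_contacts: bool = True,
                 use_gravity: bool = True):
        self.fluid = fluid
        self.geom = geom
        self.field = field
        self.contact = contact or ContactParams()
        self.use_lift = use_lift
        self.use_contacts = use_contacts
        self.use_gravity = use_gravity
        self.ids = np.array([p.id for p in particles], dtype=np.int64)
        self.pos = np.array([p.position for p in particles], dtype=float)
        self.vel = np.array([p.velocity for p in particles], dtype=float)
        self.radius = np.array([p.radius for p in particles], dtype=float)
        self.density = np.array([p.density for p in particles], dtype=float)
        if field is not None:
            self._kfields = field.kernel_fields()
            self._dr, self._dz = field.dr, field.dz
        else:
            self._kfields = np.zeros((9, 2, 2))
            self._dr = geom.radius
            self._dz = geom.height

    @property
    def n(self) -> int:
        return len(self.radius)

    def max_dt(self) -> float:
        t0_min = float(np.min(self.density * (2 * self.radius) ** 2
                              / (18.0 * self.fluid.viscosity)))
        return t0_min / 5.0

    def run(self, duration: float, dt: Optional[float] = None,
            sample_every: int = 10) -> List[Trajectory]:
        """Advance for ``duration`` seconds, sampling every few steps."""
        if dt is None:
            dt = self.max_dt()
            if self.field is not None and self.field.omega > 0:
                tip = self.field.omega * (self.field.actuator.outer_radius
                                          if self.field.actuator else
                                          self.geom.radius)
                if tip > 0:
                    dt = min(dt, 0.2 * min(self._dr, self._dz) / tip)
        if dt > self.max_dt() * (1 + 1e-12):
            raise TimeStepError(
                f"dt = {dt:.3e} s exceeds t0/5 = {self.max_dt():.3e} s")
        nsteps = int(round(duration / dt)) if duration > 0 else 0
        nsamp = 1 + nsteps // sample_every
        out_t = np.zeros(nsamp)
        out_pos = np.zeros((nsamp, self.n, 3))
        out_vel = np.zeros((nsamp, self.n, 3))
        out_ufl = np.zeros((nsamp, self.n, 3))
        cap = max(64 * self.n, 1024)
        pair_i = np.zeros(cap, dtype=np.int64)
        pair_j = np.zeros(cap, dtype=np.int64)
        code = _kernels.simulate_kernel(
            self.pos, self.vel, self.radius, self.density, self._kfields,
            self._dr, self._dz, self.geom.radius, self.geom.height,
            self.fluid.viscosity, self.fluid.density, self.fluid.gravity,
            self.contact.normal_stiffness, self.contact.damping_ratio,
            self.contact.wall_stiffness,
            self.field is not None, self.use_lift, self.use_contacts,
            self.use_gravity,
            float(dt), nsteps, int(sample_every),
            out_t, out_pos, out_vel, out_ufl, pair_i, pair_j)
        if code == _kernels.PAIR_OVERFLOW:
            raise PackingError("contact neighbour list overflow")
        if code == _kernels.NON_FINITE:
            raise IntegrityError("particle state became non-finite")
        return [Trajectory(particle_id=int(self.ids[a]),
                           radius=float(self.radius[a]),
                           density=float(self.density[a]),
                           t=out_t,
                           position=out_pos[:, a, :],
                           velocity=out_vel[:, a, :],
                           fluid_velocity=out_ufl[:, a, :])
                for a in range(self.n)]

    def step(self, dt: float, nsteps: int = 1) -> None:
        """Advance in place without sampling (unit-test convenience)."""
        if dt > self.max_dt() * (1 + 1e-12):
            raise TimeStepError(
                f"dt = {dt:.3e} s exceeds t0/5 = {self.max_dt():.3e} s")
        saved = self.run(duration=dt * nsteps, dt=dt,
                         sample_every=max(nsteps, 1))
        del saved

    def states(self) -> List[ParticleState]:
        return [ParticleState(id=int(self.ids[a]), radius=float(self.radius[a]),
                              density=float(self.density[a]),
                              position=self.pos[a].copy(),
                              velocity=self.vel[a].copy())
                for a in range(self.n)]


def step(particles: Sequence[ParticleState], field: Optional[FlowField],
         fluid: FluidProperties, geom: VesselGeometry, dt: float,
         contact: Optional[ContactParams] = None,
         **flags) -> List[ParticleState]:
    """One semi-implicit Euler step for a list of particle states."""
    susp = Suspension(particles, fluid, geom, field, contact, **flags)
    susp.step(dt)
    return susp.states()


def simulate(cfg: ProcessConfig, field: FlowField,
             size_spec: Optional[SizeDistributionSpec] = None, *,
             force: bool = False, use_lift: bool = True,
             use_contacts: bool = True) -> List[Trajectory]:
    """Run the configured suspension culture and record trajectories.

    Particle radii come from the steady-state size distribution (the
    population the flow model is meant to characterise) unless another
    spec is given; density is uniform at the configured particle density.
    Reproducible per seed: the run seed fans out to child seeds for sizes
    and placement.
    """
    report = regime_report(cfg)
    if not report.laminar_ok and not force:
        raise LaminarGateError(
            f"Re_f = {report.fluid_reynolds:.0f} fails the laminar gate")
    size_spec = size_spec or steady_state_spec()
    seeds = np.random.SeedSequence(cfg.seed).spawn(1)[0]
    particles = init_population(size_spec, cfg.n_particles,
                                seed=seeds, geom=cfg.vessel,
                                imp=cfg.impeller,
                                density=cfg.particle.density)
    susp = Suspension(particles, cfg.fluid, cfg.vessel, field, cfg.contact,
                      use_lift=use_lift, use_contacts=use_contacts)
    dt = cfg.dt
    if dt is None:
        dt = min(susp.max_dt(),
                 0.2 * min(field.dr, field.dz) / cfg.impeller.tip_speed
                 if cfg.impeller.tip_speed > 0 else susp.max_dt())
    return susp.run(cfg.duration, dt=dt, sample_every=cfg.sample_every)
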