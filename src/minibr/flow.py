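"""Steady axisymmetric Stokes flow with swirl in one miniBR well.

At the fluid Reynolds numbers of the mini-bioreactor (Re_f < 2000 by the
laminar gate, and inertia formally dropped) the flow is modelled as steady
incompressible Stokes flow in an (r, z) meridional plane. The rotating
impeller is reduced to an *actuator annulus*:

* inside the annulus the azimuthal velocity is prescribed as rigid rotation
  u_theta = omega * r (Dirichlet), which drives the swirl everywhere else
  through the azimuthal Stokes balance (Laplace-like, no forcing);
* the blade pitch pumps axially; this is represented by an axial body force
  in the annulus whose amplitude is calibrated so the volumetric flow
  through the actuator equals Q = N_q * omega * R_i^3 (upward). Because
  Stokes flow is linear, the calibration is a single exact rescaling.

At zero Reynolds number the swirl and the meridional (u_r, u_z) problems
decouple, so they are solved as two independent sparse linear systems on a
uniform grid: the swirl directly, the meridional flow in stream-function /
vorticity form (which enforces incompressibility exactly in 2D). Walls are
no-slip, the flat top is a shear-free free surface, the axis carries
symmetry conditions. Pressure is recovered from a Poisson problem driven by
the body force; it is diagnostic only (all stress queries use the
deviatoric, i.e. pressure-free, part).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from typing import Optional

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .config import FluidProperties, ImpellerSpec, VesselGeometry
from .dimensionless import fluid_reynolds, LAMINAR_THRESHOLD
from .exceptions import (CalibrationError, LaminarGateError, OutOfDomainError,
                         SolverError)

__all__ = [
    "FlowField",
    "ActuatorModel",
    "solve_flow",
    "velocity_at",
    "strain_rate_at",
    "deviatoric_stress_at",
    "fixture_fields",
    "quiescent_field",
    "solid_body_field",
    "couette_field",
]

_DOMAIN_TOL = 1e-12


@dataclass(frozen=True)
class ActuatorModel:
    """Calibrated actuator annulus standing in for the impeller."""

    inner_radius: float        # m
    outer_radius: float        # m (= impeller radius)
    z_bottom: float            # m (= hub clearance)
    z_top: float               # m (= clearance + 2 * half thickness)
    amplitude: float           # axial body-force density f_z, N/m^3
    target_flow: float         # Q = N_q omega R_i^3, m^3/s
    achieved_flow: float       # m^3/s


@dataclass
class FlowField:
    """Nodal axisymmetric velocity/pressure field plus derivative caches.

    Arrays are indexed ``[i, j]`` with ``i`` along r (0..nr-1) and ``j``
    along z (0..nz-1). Cached nodal fields: the six independent cylindrical
    strain-rate components, the vorticity vector and the steady convective
    acceleration (u . grad) u used by the particle engine.
    """

    geom: VesselGeometry
    r: np.ndarray
    z: np.ndarray
    u_r: np.ndarray
    u_theta: np.ndarray
    u_z: np.ndarray
    p: np.ndarray
    omega: float = 0.0
    actuator: Optional[ActuatorModel] = None
    strain: np.ndarray = dc_field(default=None, repr=False)   # (6, nr, nz)
    vorticity: np.ndarray = dc_field(default=None, repr=False)  # (3, nr, nz)
    acceleration: np.ndarray = dc_field(default=None, repr=False)  # (3, nr, nz)

    def __post_init__(self):
        if self.strain is None:
            self._build_caches()

    # strain component order used throughout
    STRAIN_ORDER = ("rr", "tt", "zz", "rz", "rt", "tz")

    @property
    def dr(self) -> float:
        return float(self.r[1] - self.r[0])

    @property
    def dz(self) -> float:
        return float(self.z[1] - self.z[0])

    @property
    def shape(self):
        return self.u_r.shape

    def _build_caches(self) -> None:
        r = self.r
        r_safe = r.copy()
        r_safe[0] = 1.0  # axis rows overwritten with their limits below
        rs = r_safe[:, None]

        dur_dr = np.gradient(self.u_r, self.dr, axis=0, edge_order=2)
        dur_dz = np.gradient(self.u_r, self.dz, axis=1, edge_order=2)
        dut_dr = np.gradient(self.u_theta, self.dr, axis=0, edge_order=2)
        dut_dz = np.gradient(self.u_theta, self.dz, axis=1, edge_order=2)
        duz_dr = np.gradient(self.u_z, self.dr, axis=0, edge_order=2)
        duz_dz = np.gradient(self.u_z, self.dz, axis=1, edge_order=2)

        e_rr = dur_dr
        e_tt = self.u_r / rs
        e_tt[0, :] = dur_dr[0, :]                # l'Hopital at the axis
        e_zz = duz_dz
        e_rz = 0.5 * (dur_dz + duz_dr)
        e_rt = 0.5 * (dut_dr - self.u_theta / rs)
        e_rt[0, :] = 0.0                         # u_theta ~ c r near axis
        e_tz = 0.5 * dut_dz
        self.strain = np.ascontiguousarray(
            np.stack([e_rr, e_tt, e_zz, e_rz, e_rt, e_tz]))

        w_r = -dut_dz
        w_t = dur_dz - duz_dr
        w_z = dut_dr + self.u_theta / rs
        w_z[0, :] = 2.0 * dut_dr[0, :]
        self.vorticity = np.ascontiguousarray(np.stack([w_r, w_t, w_z]))

        a_r = self.u_r * dur_dr + self.u_z * dur_dz - self.u_theta ** 2 / rs
        a_t = (self.u_r * dut_dr + self.u_z * dut_dz
               + self.u_r * self.u_theta / rs)
        a_z = self.u_r * duz_dr + self.u_z * duz_dz
        a_r[0, :] = 0.0
        a_t[0, :] = 0.0
        a_z[0, :] = self.u_z[0, :] * duz_dz[0, :]
        self.acceleration = np.ascontiguousarray(np.stack([a_r, a_t, a_z]))

    # ------------------------------------------------------------------
    # queries

    def _locate(self, rq, zq):
        rq = np.asarray(rq, dtype=float)
        zq = np.asarray(zq, dtype=float)
        geom = self.geom
        if np.any(rq < -_DOMAIN_TOL) or np.any(rq > geom.radius * (1 + 1e-9)) \
                or np.any(zq < -geom.height * 1e-9) \
                or np.any(zq > geom.height * (1 + 1e-9)):
            raise OutOfDomainError("query point outside the liquid domain")
        x = np.clip(rq / self.dr, 0.0, self.shape[0] - 1 - 1e-12)
        y = np.clip(zq / self.dz, 0.0, self.shape[1] - 1 - 1e-12)
        i = x.astype(int)
        j = y.astype(int)
        return i, j, x - i, y - j

    def _interp(self, comps: np.ndarray, rq, zq) -> np.ndarray:
        """Bilinear interpolation of stacked nodal fields (k, nr, nz)."""
        i, j, fx, fy = self._locate(rq, zq)
        c00 = comps[:, i, j]
        c10 = comps[:, i + 1, j]
        c01 = comps[:, i, j + 1]
        c11 = comps[:, i + 1, j + 1]
        return (c00 * (1 - fx) * (1 - fy) + c10 * fx * (1 - fy)
                + c01 * (1 - fx) * fy + c11 * fx * fy)

    def velocity_cyl(self, rq, zq) -> np.ndarray:
        """(u_r, u_theta, u_z) at (r, z), bilinearly interpolated."""
        return self._interp(np.stack([self.u_r, self.u_theta, self.u_z]),
                            rq, zq)

    def kernel_fields(self) -> np.ndarray:
        """Stacked (9, nr, nz) array for the particle kernel:
        u_r, u_theta, u_z, vorticity (3), convective acceleration (3)."""
        return np.ascontiguousarray(np.concatenate([
            np.stack([self.u_r, self.u_theta, self.u_z]),
            self.vorticity, self.acceleration]))

    def max_divergence(self) -> float:
        """Max |(1/r) d(r u_r)/dr + d(u_z)/dz| over interior nodes (1/s)."""
        r = self.r[:, None]
        ru_r = r * self.u_r
        div = (np.gradient(ru_r, self.dr, axis=0, edge_order=2)
               / np.where(r > 0, r, 1.0)
               + np.gradient(self.u_z, self.dz, axis=1, edge_order=2))
        return float(np.abs(div[1:-1, 1:-1]).max())

    def kinetic_energy(self) -> float:
        """Domain-integrated 0.5 |u|^2 dV (per unit density), m^5/s^2."""
        u2 = self.u_r ** 2 + self.u_theta ** 2 + self.u_z ** 2
        integrand = 0.5 * u2 * 2.0 * math.pi * self.r[:, None]
        return float(np.trapezoid(np.trapezoid(integrand, self.z, axis=1),
                                  self.r))


def velocity_at(field: FlowField, point) -> np.ndarray:
    """Cartesian velocity at a cylindrical point (r, theta, z).

    The axisymmetric nodal field is interpolated bilinearly in (r, z) and
    rotated into Cartesian components at azimuth theta. Nodal values are
    reproduced exactly at nodes.
    """
    rq, theta, zq = point
    ur, ut, uz = field.velocity_cyl(rq, zq)
    c, s = math.cos(theta), math.sin(theta)
    return np.array([ur * c - ut * s, ur * s + ut * c, uz])


def strain_rate_at(field: FlowField, point) -> np.ndarray:
    """Full symmetric strain-rate tensor (1/s) in cylindrical components.

    Rows/columns ordered (r, theta, z); includes the swirl couplings
    E_rt = (du_theta/dr - u_theta/r)/2 and E_tz = (du_theta/dz)/2.
    """
    rq, _, zq = point
    e_rr, e_tt, e_zz, e_rz, e_rt, e_tz = field._interp(field.strain, rq, zq)
    return np.array([[e_rr, e_rt, e_rz],
                     [e_rt, e_tt, e_tz],
                     [e_rz, e_tz, e_zz]])


def deviatoric_stress_at(field: FlowField, fluid: FluidProperties,
                         point) -> np.ndarray:
    """Newtonian deviatoric stress tau = 2 mu_f E at a point (Pa)."""
    return 2.0 * fluid.viscosity * strain_rate_at(field, point)


# --------------------------------------------------------------------------
# solver

def _idx(i, j, nz):
    return i * nz + j


def solve_flow(geom: VesselGeometry, fluid: FluidProperties,
               imp: ImpellerSpec, resolution=(64, 96), *,
               force: bool = False) -> FlowField:
    """Solve the steady axisymmetric Stokes problem for one well.

    Raises :class:`LaminarGateError` when Re_f >= 2000 unless ``force``.
    """
    imp.validate_against(geom)
    re_f = fluid_reynolds(fluid, imp.angular_velocity, imp.radius)
    if re_f >= LAMINAR_THRESHOLD and not force:
        raise LaminarGateError(
            f"Re_f = {re_f:.0f} >= {LAMINAR_THRESHOLD:.0f}: flow may not be "
            "laminar; pass force=True to override")

    nr, nz = resolution
    r = np.linspace(0.0, geom.radius, nr)
    z = np.linspace(0.0, geom.height, nz)
    dr, dz = r[1] - r[0], z[1] - z[0]

    omega = imp.angular_velocity
    zeros = np.zeros((nr, nz))
    if omega == 0.0:
        act = ActuatorModel(imp.hub_radius, imp.radius, imp.clearance,
                            imp.clearance + 2 * imp.half_thickness,
                            0.0, 0.0, 0.0)
        return FlowField(geom, r, z, zeros.copy(), zeros.copy(),
                         zeros.copy(), zeros.copy(), omega=0.0, actuator=act)

    z_bot = imp.clearance
    z_top = imp.clearance + 2.0 * imp.half_thickness
    in_annulus = ((r[:, None] >= imp.hub_radius) & (r[:, None] <= imp.radius)
                  & (z[None, :] >= z_bot) & (z[None, :] <= z_top))

    u_theta = _solve_swirl(r, z, dr, dz, in_annulus, omega)
    psi, eta, amplitude, q_hat = _solve_meridional(
        r, z, dr, dz, in_annulus, fluid.viscosity, imp)
    u_rf, u_zf = _velocities_from_psi(psi, r, dr, dz)
    p = _solve_pressure(r, z, dr, dz, in_annulus, amplitude)

    act = ActuatorModel(imp.hub_radius, imp.radius, z_bot, z_top,
                        amplitude, imp.target_flow, q_hat)
    return FlowField(geom, r, z, u_rf, u_theta, u_zf, p,
                     omega=omega, actuator=act)


def _solve_swirl(r, z, dr, dz, in_annulus, omega):
    """Azimuthal Stokes balance: L u_theta - u_theta / r^2 = 0."""
    nr, nz = len(r), len(z)
    rows, cols, vals, rhs = [], [], [], np.zeros(nr * nz)

    def add(rw, cl, v):
        rows.append(rw); cols.append(cl); vals.append(v)

    for i in range(nr):
        for j in range(nz):
            k = _idx(i, j, nz)
            if in_annulus[i, j]:
                add(k, k, 1.0)
                rhs[k] = omega * r[i]
            elif i == 0 or i == nr - 1 or j == 0:
                add(k, k, 1.0)          # axis and no-slip walls: u_theta = 0
            elif j == nz - 1:           # shear-free top: du_theta/dz = 0
                add(k, k, 3.0)
                add(k, _idx(i, nz - 2, nz), -4.0)
                add(k, _idx(i, nz - 3, nz), 1.0)
            else:
                ri = r[i]
                add(k, _idx(i + 1, j, nz), 1.0 / dr ** 2 + 1.0 / (2 * ri * dr))
                add(k, _idx(i - 1, j, nz), 1.0 / dr ** 2 - 1.0 / (2 * ri * dr))
                add(k, _idx(i, j + 1, nz), 1.0 / dz ** 2)
                add(k, _idx(i, j - 1, nz), 1.0 / dz ** 2)
                add(k, k, -2.0 / dr ** 2 - 2.0 / dz ** 2 - 1.0 / ri ** 2)

    mat = sp.csr_matrix((vals, (rows, cols)), shape=(nr * nz, nr * nz))
    try:
        sol = spla.spsolve(mat, rhs)
    except Exception as exc:  # pragma: no cover
        raise SolverError(f"swirl solve failed on {nr}x{nz} grid: {exc}")
    if not np.all(np.isfinite(sol)):
        raise SolverError(f"swirl solve produced non-finite values "
                          f"on {nr}x{nz} grid")
    return sol.reshape(nr, nz)


def _solve_meridional(r, z, dr, dz, in_annulus, mu, imp: ImpellerSpec):
    """Stream-function / vorticity system driven by the actuator body force.

    Unknowns x = [psi, eta]; interior equations E^2 psi = r eta and
    mu (L eta - eta/r^2) = d f_z / dr, with Thom's no-slip closure for the
    wall vorticity. The unit-amplitude solution is rescaled so the flux
    through the actuator equals the target Q (exact, by linearity).
    """
    nr, nz = len(r), len(z)
    n = nr * nz
    f_unit = np.where(in_annulus, 1.0, 0.0)
    s = np.gradient(f_unit, dr, axis=0, edge_order=2)  # d f_z / d r

    rows, cols, vals = [], [], []
    rhs = np.zeros(2 * n)

    def add(rw, cl, v):
        rows.append(rw); cols.append(cl); vals.append(v)

    for i in range(nr):
        ri = r[i]
        for j in range(nz):
            k = _idx(i, j, nz)
            # --- psi rows ---
            if i == 0 or i == nr - 1 or j == 0 or j == nz - 1:
                add(k, k, 1.0)  # psi = 0 on axis, walls and free surface
            else:
                add(k, _idx(i + 1, j, nz), 1.0 / dr ** 2 - 1.0 / (2 * ri * dr))
                add(k, _idx(i - 1, j, nz), 1.0 / dr ** 2 + 1.0 / (2 * ri * dr))
                add(k, _idx(i, j + 1, nz), 1.0 / dz ** 2)
                add(k, _idx(i, j - 1, nz), 1.0 / dz ** 2)
                add(k, k, -2.0 / dr ** 2 - 2.0 / dz ** 2)
                add(k, n + k, -ri)
            # --- eta rows ---
            ke = n + k
            if i == 0 or j == nz - 1:
                add(ke, ke, 1.0)        # axis symmetry / shear-free surface
            elif j == 0:                # bottom wall: Thom's formula
                add(ke, ke, 1.0)
                add(ke, _idx(i, 1, nz), -2.0 / (ri * dz ** 2))
            elif i == nr - 1:           # side wall: Thom's formula
                add(ke, ke, 1.0)
                add(ke, _idx(nr - 2, j, nz), -2.0 / (ri * dr ** 2))
            else:
                add(ke, n + _idx(i + 1, j, nz),
                    mu * (1.0 / dr ** 2 + 1.0 / (2 * ri * dr)))
                add(ke, n + _idx(i - 1, j, nz),
                    mu * (1.0 / dr ** 2 - 1.0 / (2 * ri * dr)))
                add(ke, n + _idx(i, j + 1, nz), mu / dz ** 2)
                add(ke, n + _idx(i, j - 1, nz), mu / dz ** 2)
                add(ke, ke, mu * (-2.0 / dr ** 2 - 2.0 / dz ** 2
                                  - 1.0 / ri ** 2))
                rhs[ke] = s[i, j]

    mat = sp.csr_matrix((vals, (rows, cols)), shape=(2 * n, 2 * n))
    try:
        sol = spla.spsolve(mat, rhs)
    except Exception as exc:  # pragma: no cover
        raise SolverError(f"meridional solve failed: {exc}")
    if not np.all(np.isfinite(sol)):
        raise SolverError("meridional solve produced non-finite values")
    psi = sol[:n].reshape(nr, nz)
    eta = sol[n:].reshape(nr, nz)

    # flux through the actuator at its mid-plane (upward positive)
    j_c = int(round((imp.clearance + imp.half_thickness) / dz))
    i_in = int(np.searchsorted(r, imp.hub_radius))
    i_out = int(np.searchsorted(r, imp.radius, side="right")) - 1
    q_unit = 2.0 * math.pi * (psi[i_in, j_c] - psi[i_out, j_c])
    if abs(q_unit) < 1e-300:
        raise CalibrationError("unit body force produced no actuator flux")
    amplitude = imp.target_flow / q_unit
    return psi * amplitude, eta * amplitude, amplitude, imp.target_flow


def _velocities_from_psi(psi, r, dr, dz):
    """u_r = (1/r) dpsi/dz, u_z = -(1/r) dpsi/dr, with axis/wall limits."""
    nr = len(r)
    r_safe = np.where(r > 0, r, 1.0)[:, None]
    u_r = np.gradient(psi, dz, axis=1, edge_order=2) / r_safe
    u_z = -np.gradient(psi, dr, axis=0, edge_order=2) / r_safe
    u_r[0, :] = 0.0
    u_r[-1, :] = 0.0
    u_r[:, 0] = 0.0
    u_z[0, :] = -2.0 * psi[1, :] / dr ** 2   # limit of -(1/r) dpsi/dr, psi ~ c r^2
    u_z[-1, :] = 0.0
    u_z[:, 0] = 0.0
    u_z[:, -1] = 0.0
    return u_r, u_z


def _solve_pressure(r, z, dr, dz, in_annulus, amplitude):
    """Poisson problem div(grad p) = div(f), homogeneous Neumann walls.

    The viscous contribution to the wall-normal pressure gradient is
    neglected in the boundary condition, so p is an approximation; it is
    written to output files but never used in stress evaluation.
    """
    nr, nz = len(r), len(z)
    f_z = np.where(in_annulus, amplitude, 0.0)
    src = np.gradient(f_z, dz, axis=1, edge_order=2)

    rows, cols, vals = [], [], []
    rhs = np.zeros(nr * nz)

    def add(rw, cl, v):
        rows.append(rw); cols.append(cl); vals.append(v)

    for i in range(nr):
        ri = r[i]
        for j in range(nz):
            k = _idx(i, j, nz)
            if i == 0 and j == 0:
                add(k, k, 1.0)          # gauge: p = 0 at the axis-bottom node
            elif i == 0:
                add(k, k, 1.0)
                add(k, _idx(1, j, nz), -1.0)
            elif i == nr - 1:
                add(k, k, 1.0)
                add(k, _idx(nr - 2, j, nz), -1.0)
            elif j == 0:
                add(k, k, 1.0)
                add(k, _idx(i, 1, nz), -1.0)
            elif j == nz - 1:
                add(k, k, 1.0)
                add(k, _idx(i, nz - 2, nz), -1.0)
            else:
                add(k, _idx(i + 1, j, nz), 1.0 / dr ** 2 + 1.0 / (2 * ri * dr))
                add(k, _idx(i - 1, j, nz), 1.0 / dr ** 2 - 1.0 / (2 * ri * dr))
                add(k, _idx(i, j + 1, nz), 1.0 / dz ** 2)
                add(k, _idx(i, j - 1, nz), 1.0 / dz ** 2)
                add(k, k, -2.0 / dr ** 2 - 2.0 / dz ** 2)
                rhs[k] = src[i, j]

    mat = sp.csr_matrix((vals, (rows, cols)), shape=(nr * nz, nr * nz))
    p = spla.spsolve(mat, rhs).reshape(nr, nz)
    return p - p.mean()


# --------------------------------------------------------------------------
# analytic fixtures (test oracles and fixture-mode particle runs)

def _fixture_grid(geom, resolution):
    geom = geom or VesselGeometry()
    nr, nz = resolution
    r = np.linspace(0.0, geom.radius, nr)
    z = np.linspace(0.0, geom.height, nz)
    return geom, r, z


def quiescent_field(geom: Optional[VesselGeometry] = None,
                    resolution=(32, 48)) -> FlowField:
    """Fluid at rest everywhere."""
    geom, r, z = _fixture_grid(geom, resolution)
    zeros = np.zeros((len(r), len(z)))
    return FlowField(geom, r, z, zeros.copy(), zeros.copy(), zeros.copy(),
                     zeros.copy())


def solid_body_field(omega: float, geom: Optional[VesselGeometry] = None,
                     resolution=(32, 48)) -> FlowField:
    """Rigid rotation u_theta = omega r: rotation without deformation."""
    geom, r, z = _fixture_grid(geom, resolution)
    zeros = np.zeros((len(r), len(z)))
    u_theta = np.broadcast_to(omega * r[:, None], zeros.shape).copy()
    return FlowField(geom, r, z, zeros.copy(), u_theta, zeros.copy(),
                     zeros.copy(), omega=omega)


def couette_field(gdot: float, geom: Optional[VesselGeometry] = None,
                  resolution=(32, 48)) -> FlowField:
    """Uniform simple shear, axisymmetric analog u_z = gdot * r.

    The only non-zero strain component is E_rz = gdot / 2, so a probe held
    anywhere sees the planar-Couette von Mises stress sqrt(3) mu gdot.
    """
    geom, r, z = _fixture_grid(geom, resolution)
    zeros = np.zeros((len(r), len(z)))
    u_z = np.broadcast_to(gdot * r[:, None], zeros.shape).copy()
    return FlowField(geom, r, z, zeros.copy(), zeros.copy(), u_z,
                     zeros.copy())


def fixture_fields(omega: float = 13.0, gdot: float = 10.0,
                   geom: Optional[VesselGeometry] = None,
                   resolution=(32, 48)) -> dict:
    """The three named analytic fixtures keyed by name."""
    return {
        "quiescent": quiescent_field(geom, resolution),
        "solid_body": solid_body_field(omega, geom, resolution),
        "couette": couette_field(gdot, geom, resolution),
    }
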