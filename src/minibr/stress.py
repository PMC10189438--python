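"""Per-microtissue von Mises stress statistics.

The mechanical dose reported for each microtissue is the von Mises
invariant of the *fluid* deviatoric stress evaluated at the particle
center, sigma_vM = sqrt(3 J2) with J2 = tau:tau / 2, averaged over the
particle's trajectory with trapezoidal time weighting. Contact stresses
are excluded by default (at ~0.1% volume fraction they barely register; a
toggle exists for sensitivity checks at the trace level).

A particle is classified *stagnant* when, over the final half of its
trajectory, its mean height stays below the impeller plane (the hub
clearance) and its mean speed stays below 5% of the impeller tip speed;
otherwise it is *recirculating*. Sweeping the relative excess density
delta = (rho_p - rho_f)/rho_f maps out how long a persistent stagnant
sub-impeller population (>= 5% of particles by default) survives.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from typing import List, Optional, Sequence

import numpy as np

from .config import (FluidProperties, ImpellerSpec, ProcessConfig,
                     VesselGeometry)
from .exceptions import (ClassificationError, EmptyPopulationError,
                         InvalidParameterError, InvalidTensorError)
from .flow import FlowField, solve_flow
from .suspension import Trajectory, simulate

__all__ = [
    "StressTrace",
    "PopulationSummary",
    "SweepResult",
    "von_mises",
    "stress_history",
    "population_summary",
    "classify",
    "density_sweep",
    "STAGNANT_SPEED_FRACTION",
    "PERSISTENCE_THRESHOLD",
]

#: A particle slower (on average) than this fraction of tip speed can be
#: stagnant (the second criterion is being below the impeller plane).
STAGNANT_SPEED_FRACTION = 0.05

#: A stagnant population is "persistent" when it holds at least this
#: fraction of all particles.
PERSISTENCE_THRESHOLD = 0.05

PERCENTILES = (5, 25, 50, 75, 95)


@dataclass
class StressTrace:
    """Instantaneous von Mises stress along one trajectory plus its
    time-weighted trajectory average (the reported per-microtissue dose)."""

    particle_id: int
    t: np.ndarray
    von_mises: np.ndarray   # Pa, >= 0
    average: float          # Pa, trapezoidal time-weighted mean


@dataclass
class PopulationSummary:
    """Distribution of trajectory-averaged stresses for one regime."""

    regime: Optional[str]
    averages: np.ndarray        # Pa, one entry per particle
    percentiles: dict           # {5: ..., 25: ..., 50: ..., 75: ..., 95: ...}
    stagnant_fraction: float

    @property
    def median(self) -> float:
        return self.percentiles[50]


@dataclass
class SweepResult:
    """Stagnant-fraction curve over relative excess density."""

    deltas: np.ndarray
    stagnant_fractions: np.ndarray
    threshold: float
    critical_delta: Optional[float]   # largest delta with fraction >= threshold
    beyond_range: bool                # loss of persistence not bracketed


def von_mises(tau: np.ndarray, trace_tol: float = 1e-9) -> float:
    """sigma_vM = sqrt(1.5 * sum tau_ij^2) of a symmetric deviatoric tensor.

    Raises for asymmetric input or a trace exceeding ``trace_tol`` relative
    to the tensor magnitude.
    """
    tau = np.asarray(tau, dtype=float)
    if tau.shape != (3, 3):
        raise InvalidTensorError(f"expected 3x3 tensor, got {tau.shape}")
    scale = float(np.abs(tau).max())
    if scale > 0.0:
        if float(np.abs(tau - tau.T).max()) > 1e-9 * scale:
            raise InvalidTensorError("stress tensor is not symmetric")
        if abs(float(np.trace(tau))) > max(trace_tol * scale, 1e-300):
            raise InvalidTensorError("stress tensor is not deviatoric")
    return math.sqrt(1.5 * float(np.sum(tau * tau)))


def _vm_along_path(field: FlowField, fluid: FluidProperties,
                   rq: np.ndarray, zq: np.ndarray) -> np.ndarray:
    """Vectorized von Mises of 2 mu E along interpolated path points."""
    e = field._interp(field.strain, rq, zq)   # (6, m): rr, tt, zz, rz, rt, tz
    sumsq = (e[0] ** 2 + e[1] ** 2 + e[2] ** 2
             + 2.0 * (e[3] ** 2 + e[4] ** 2 + e[5] ** 2))
    return 2.0 * fluid.viscosity * np.sqrt(1.5 * sumsq)


def stress_history(traj: Trajectory, field: FlowField,
                   fluid: FluidProperties) -> StressTrace:
    """Evaluate the fluid von Mises stress along a recorded trajectory."""
    rq = np.hypot(traj.position[:, 0], traj.position[:, 1])
    zq = traj.position[:, 2]
    vm = _vm_along_path(field, fluid, rq, zq)
    if len(traj.t) > 1:
        avg = float(np.trapezoid(vm, traj.t) / (traj.t[-1] - traj.t[0]))
    else:
        avg = float(vm[0])
    return StressTrace(particle_id=traj.particle_id, t=traj.t,
                       von_mises=vm, average=avg)


def classify(trajectories: Sequence[Trajectory], geom: VesselGeometry,
             imp: ImpellerSpec,
             speed_fraction: float = STAGNANT_SPEED_FRACTION,
             min_duration: float = 10.0) -> np.ndarray:
    """Label each trajectory ``"stagnant"`` or ``"recirculating"``.

    Uses the final half of each trajectory; requires at least
    ``min_duration`` seconds of simulated time.
    """
    labels = []
    for traj in trajectories:
        if traj.duration < min_duration:
            raise ClassificationError(
                f"trajectory of particle {traj.particle_id} spans only "
                f"{traj.duration:.1f} s (< {min_duration} s)")
        half = traj.t >= traj.t[0] + 0.5 * traj.duration
        mean_height = float(np.mean(traj.position[half, 2]))
        mean_speed = float(np.mean(
            np.linalg.norm(traj.velocity[half], axis=1)))
        stagnant = (mean_height < imp.clearance
                    and mean_speed < speed_fraction * imp.tip_speed)
        labels.append("stagnant" if stagnant else "recirculating")
    return np.array(labels)


def population_summary(traces: Sequence[StressTrace],
                       trajectories: Sequence[Trajectory],
                       geom: VesselGeometry, imp: ImpellerSpec,
                       regime: Optional[str] = None) -> PopulationSummary:
    """Percentiles of trajectory-averaged stress plus the stagnant split."""
    if len(traces) == 0:
        raise EmptyPopulationError("no stress traces supplied")
    averages = np.array([tr.average for tr in traces])
    pct = {p: float(np.percentile(averages, p)) for p in PERCENTILES}
    labels = classify(trajectories, geom, imp)
    frac = float(np.mean(labels == "stagnant"))
    return PopulationSummary(regime=regime, averages=averages,
                             percentiles=pct, stagnant_fraction=frac)


def density_sweep(cfg: ProcessConfig, deltas: Sequence[float],
                  persistence_threshold: float = PERSISTENCE_THRESHOLD,
                  field: Optional[FlowField] = None,
                  **simulate_kwargs) -> SweepResult:
    """Stagnant-population persistence over relative excess density.

    Each delta re-runs the suspension with the same seed (common initial
    population) and particle density rho_f (1 + delta); the critical
    density is the largest delta whose stagnant fraction still reaches the
    persistence threshold.
    """
    deltas = np.asarray(list(deltas), dtype=float)
    if deltas.size < 1:
        raise InvalidParameterError("delta sweep needs at least one entry")
    if np.any(np.diff(deltas) <= 0):
        raise InvalidParameterError("delta list must be strictly increasing")
    if field is None:
        field = solve_flow(cfg.vessel, cfg.fluid, cfg.impeller,
                           resolution=cfg.grid)
    fractions = []
    for delta in deltas:
        sub = cfg.with_delta(float(delta))
        trajs = simulate(sub, field, **simulate_kwargs)
        labels = classify(trajs, cfg.vessel, cfg.impeller)
        fractions.append(float(np.mean(labels == "stagnant")))
    fractions = np.array(fractions)
    qualifying = deltas[fractions >= persistence_threshold]
    if qualifying.size:
        critical = float(qualifying[-1])
        beyond = bool(critical == deltas[-1])
    else:
        critical = None
        beyond = True
    return SweepResult(deltas=deltas, stagnant_fractions=fractions,
                       threshold=persistence_threshold,
                       critical_delta=critical, beyond_range=beyond)
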