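"""Von Mises stress invariant, trajectory stress histories and population
statistics."""

import math

import numpy as np
import pytest

import minibr as mb
from minibr.exceptions import (ClassificationError, EmptyPopulationError,
                               InvalidTensorError)

FLUID = mb.FluidProperties()
GEOM = mb.VesselGeometry()
IMP = mb.ImpellerSpec(angular_velocity=13.0)


class TestVonMises:
    def test_zero_tensor(self):
        assert mb.von_mises(np.zeros((3, 3))) == 0.0

    def test_simple_shear_closed_form(self):
        """Simple shear at mu = 1e-3, gdot = 10/s: sqrt(3) mu gdot."""
        tau = np.zeros((3, 3))
        tau[0, 1] = tau[1, 0] = 1e-3 * 10.0
        assert mb.von_mises(tau) == pytest.approx(math.sqrt(3) * 1e-2,
                                                  rel=1e-12)

    def test_uniaxial_extension_closed_form(self):
        """Uniaxial extension rate 1/s at mu = 7e-4: 3 mu edot."""
        mu, edot = 7e-4, 1.0
        tau = 2 * mu * edot * np.diag([1.0, -0.5, -0.5])
        assert mb.von_mises(tau) == pytest.approx(3 * mu * edot, rel=1e-12)

    def test_asymmetric_tensor_rejected(self):
        bad = np.zeros((3, 3))
        bad[0, 1] = 1.0
        with pytest.raises(InvalidTensorError):
            mb.von_mises(bad)

    def test_non_deviatoric_tensor_rejected(self):
        with pytest.raises(InvalidTensorError):
            mb.von_mises(np.eye(3))


class TestStressHistory:
    def _parked_trajectory(self, pos, duration=20.0, n=41):
        t = np.linspace(0.0, duration, n)
        x = np.tile(np.asarray(pos, float), (n, 1))
        z = np.zeros((n, 3))
        return mb.Trajectory(0, 60e-6, FLUID.density, t, x, z, z)

    def test_quiescent_fluid_gives_zero_trace(self):
        f = mb.quiescent_field(GEOM)
        tr = mb.stress_history(self._parked_trajectory([3e-3, 0, 5e-3]),
                               f, FLUID)
        assert not np.any(tr.von_mises) and tr.average == 0.0

    def test_rigid_rotation_gives_zero_trace(self):
        """A particle circling in solid-body rotation feels no deformation
        and hence no stress."""
        f = mb.solid_body_field(13.0, GEOM)
        n, r0 = 41, 3e-3
        t = np.linspace(0, 20, n)
        ang = 13.0 * t
        pos = np.stack([r0 * np.cos(ang), r0 * np.sin(ang),
                        np.full(n, 5e-3)], axis=1)
        traj = mb.Trajectory(0, 60e-6, FLUID.density, t, pos,
                             np.zeros((n, 3)), np.zeros((n, 3)))
        tr = mb.stress_history(traj, f, FLUID)
        assert np.abs(tr.von_mises).max() < 1e-12

    def test_couette_constant_trace_and_average(self):
        """Held fixed in gdot = 10/s Couette at mu = 1e-3: constant
        17.32 mPa, trajectory average equal to it."""
        fluid = mb.FluidProperties(density=1000.0, viscosity=1e-3)
        f = mb.couette_field(10.0, GEOM)
        tr = mb.stress_history(self._parked_trajectory([4e-3, 0, 6e-3]),
                               f, fluid)
        expected = math.sqrt(3) * 1e-3 * 10.0
        assert np.allclose(tr.von_mises, expected, rtol=1e-9)
        assert tr.average == pytest.approx(expected, rel=1e-9)

    def test_time_weighted_average_uses_trapezoid(self):
        f = mb.couette_field(10.0, GEOM)
        n = 5
        t = np.array([0.0, 1.0, 2.0, 3.0, 10.0])
        pos = np.tile([4e-3, 0.0, 6e-3], (n, 1))
        traj = mb.Trajectory(0, 60e-6, FLUID.density, t, pos,
                             np.zeros((n, 3)), np.zeros((n, 3)))
        tr = mb.stress_history(traj, f, FLUID)
        # constant stress: any correct time weighting returns the constant
        assert tr.average == pytest.approx(tr.von_mises[0], rel=1e-12)


class TestClassify:
    def _fixture_population(self, n_stagnant, n_recirc):
        trajs = []
        t = np.linspace(0, 20, 81)
        m = len(t)
        for k in range(n_stagnant):
            pos = np.tile([5e-3, 0, 100e-6], (m, 1))
            trajs.append(mb.Trajectory(k, 60e-6, 1043.0, t, pos,
                                       np.zeros((m, 3)), np.zeros((m, 3))))
        for k in range(n_recirc):
            ang = 2 * np.pi * t / 5.0
            pos = np.stack([3e-3 * np.cos(ang), 3e-3 * np.sin(ang),
                            np.full(m, 8e-3)], axis=1)
            vel = np.gradient(pos, t, axis=0)
            trajs.append(mb.Trajectory(n_stagnant + k, 60e-6, 1043.0, t,
                                       pos, vel, np.zeros((m, 3))))
        return trajs

    def test_resting_particle_is_stagnant(self):
        labels = mb.classify(self._fixture_population(1, 0), GEOM, IMP)
        assert labels[0] == "stagnant"

    def test_fast_looping_particle_is_recirculating(self):
        labels = mb.classify(self._fixture_population(0, 1), GEOM, IMP)
        assert labels[0] == "recirculating"

    def test_constructed_half_half_population(self):
        trajs = self._fixture_population(5, 5)
        labels = mb.classify(trajs, GEOM, IMP)
        assert np.mean(labels == "stagnant") == pytest.approx(0.5)

    def test_short_trajectory_rejected(self):
        t = np.linspace(0, 2, 11)
        pos = np.tile([3e-3, 0, 5e-3], (11, 1))
        traj = mb.Trajectory(0, 60e-6, 1043.0, t, pos, np.zeros((11, 3)),
                             np.zeros((11, 3)))
        with pytest.raises(ClassificationError):
            mb.classify([traj], GEOM, IMP)


class TestPopulationSummary:
    def _trace(self, pid, value):
        t = np.linspace(0, 20, 11)
        return mb.StressTrace(pid, t, np.full(11, value), value)

    def _flat_trajs(self, n):
        t = np.linspace(0, 20, 11)
        pos = np.tile([5e-3, 0, 100e-6], (11, 1))
        return [mb.Trajectory(k, 60e-6, 1043.0, t, pos, np.zeros((11, 3)),
                              np.zeros((11, 3))) for k in range(n)]

    def test_uniform_population_percentiles(self):
        traces = [self._trace(k, 2e-3) for k in range(4)]
        s = mb.population_summary(traces, self._flat_trajs(4), GEOM, IMP)
        assert all(v == pytest.approx(2e-3) for v in s.percentiles.values())

    def test_two_particle_median(self):
        traces = [self._trace(0, 1e-3), self._trace(1, 3e-3)]
        s = mb.population_summary(traces, self._flat_trajs(2), GEOM, IMP)
        assert s.median == pytest.approx(2e-3)

    def test_percentiles_monotone(self, small_run):
        cfg, field, trajs = small_run
        traces = [mb.stress_history(t, field, cfg.fluid) for t in trajs]
        s = mb.population_summary(traces, trajs, cfg.vessel, cfg.impeller)
        vals = [s.percentiles[p] for p in (5, 25, 50, 75, 95)]
        assert all(a <= b for a, b in zip(vals, vals[1:]))
        assert 0.0 <= s.stagnant_fraction <= 1.0

    def test_empty_population_rejected(self):
        with pytest.raises(EmptyPopulationError):
            mb.population_summary([], [], GEOM, IMP)


class TestOmegaScaling:
    def test_trajectory_averaged_stress_scales_with_omega(self):
        """With neutral particles, doubling omega doubles every
        trajectory-averaged stress (Stokes linearity, matched steps)."""
        i1 = mb.ImpellerSpec(angular_velocity=6.5)
        i2 = mb.ImpellerSpec(angular_velocity=13.0)
        f1 = mb.solve_flow(GEOM, FLUID, i1, resolution=(32, 48))
        f2 = mb.solve_flow(GEOM, FLUID, i2, resolution=(32, 48))
        cfg1 = mb.ProcessConfig(impeller=i1, n_particles=20, seed=21,
                                duration=8.0, dt=2e-4, sample_every=100,
                                grid=(32, 48)).with_delta(0.0)
        cfg2 = mb.ProcessConfig(impeller=i2, n_particles=20, seed=21,
                                duration=4.0, dt=1e-4, sample_every=100,
                                grid=(32, 48)).with_delta(0.0)
        t1 = mb.simulate(cfg1, f1)
        t2 = mb.simulate(cfg2, f2)
        a1 = np.array([mb.stress_history(t, f1, FLUID).average for t in t1])
        a2 = np.array([mb.stress_history(t, f2, FLUID).average for t in t2])
        assert np.all(np.abs(a2 - 2 * a1) <= 0.02 * np.abs(a2) + 1e-12)


class TestStressEnvelope:
    def test_reported_stresses_within_sanity_bound(self, small_run):
        """All trajectory-averaged stresses stay below the Couette-gap
        bound sqrt(3) mu omega Ri / (Rw - Ri) ~ O(10 mPa)."""
        cfg, field, trajs = small_run
        traces = [mb.stress_history(t, field, cfg.fluid) for t in trajs]
        bound = 0.1  # 100 mPa
        for tr in traces:
            assert 0.0 <= tr.average < bound
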