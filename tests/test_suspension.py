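"""Center-based suspension model: force laws, integration oracles,
population initialisation and containment."""

import math

import numpy as np
import pytest

import minibr as mb
from minibr.exceptions import (InvalidParameterError, PackingError,
                               TimeStepError)

FLUID = mb.FluidProperties()
GEOM = mb.VesselGeometry()


def particle(rp=60e-6, delta=0.05, pos=(3e-3, 0, 5e-3), vel=(0, 0, 0)):
    return mb.ParticleState(0, rp, FLUID.density * (1 + delta),
                            np.array(pos, float), np.array(vel, float))


class TestForceLaws:
    def test_drag_vanishes_when_comoving(self):
        p = particle(vel=(1e-3, 0, 0))
        assert not np.any(mb.drag(p, [1e-3, 0, 0], FLUID))

    def test_drag_magnitude_and_direction(self):
        p = particle()
        f = mb.drag(p, [1e-3, 0, 0], FLUID)
        assert np.linalg.norm(f) == pytest.approx(
            6 * math.pi * 7e-4 * 60e-6 * 1e-3, rel=1e-12)   # ~7.9e-10 N
        assert f[0] > 0 and f[1] == 0 and f[2] == 0

    def test_lift_zero_without_slip_or_shear(self):
        p = particle(vel=(1e-3, 0, 0))
        assert not np.any(mb.lift(p, [1e-3, 0, 0], [0, 0, 10.0], FLUID))
        p2 = particle()
        assert not np.any(mb.lift(p2, [1e-3, 0, 0], [0, 0, 0], FLUID))

    def test_lift_much_smaller_than_drag(self):
        """At the settling slip in a 10/s shear, lift is a small fraction
        of drag — the tracer assumption is force-consistent."""
        p = particle()
        slip = 5.6e-4
        fl = mb.lift(p, [slip, 0, 0], [0, 10.0, 0], FLUID)
        fd = mb.drag(p, [slip, 0, 0], FLUID)
        assert np.linalg.norm(fl) < 0.15 * np.linalg.norm(fd)
        # perpendicular to the slip direction
        assert abs(fl @ np.array([1.0, 0, 0])) < 1e-18

    def test_buoyant_weight_value_and_sign(self):
        p = particle()
        f = mb.buoyant_weight(p, FLUID)
        assert f[2] == pytest.approx(-4.41e-10, rel=5e-3)
        light = particle(delta=-0.05)
        assert mb.buoyant_weight(light, FLUID)[2] > 0
        neutral = particle(delta=0.0)
        assert not np.any(mb.buoyant_weight(neutral, FLUID))

    def test_contacts_zero_without_overlap_and_newton_third_law(self):
        a = particle(pos=(0, 0, 5e-3))
        b = particle(pos=(200e-6, 0, 5e-3))
        f = mb.contacts([a, b], GEOM)
        assert not np.any(f)
        b2 = particle(pos=(100e-6, 0, 5e-3))
        f2 = mb.contacts([a, b2], GEOM)
        assert np.allclose(f2[0], -f2[1])
        assert f2[0, 0] < 0  # pushed apart

    def test_contact_magnitude_is_stiffness_times_overlap(self):
        params = mb.ContactParams(normal_stiffness=1e-2, damping_ratio=0.0)
        a = particle(pos=(0, 0, 5e-3))
        b = particle(pos=(100e-6, 0, 5e-3))
        f = mb.contacts([a, b], GEOM, params)
        overlap = 2 * 60e-6 - 100e-6
        assert np.linalg.norm(f[0]) == pytest.approx(1e-2 * overlap,
                                                     rel=1e-12)


class TestInitPopulation:
    def test_single_particle_inside_domain(self):
        pop = mb.init_population(mb.steady_state_spec(), 1, seed=0, geom=GEOM)
        x, y, z = pop[0].position
        assert math.hypot(x, y) <= GEOM.radius and 0 <= z <= GEOM.height

    def test_determinism(self):
        a = mb.init_population(mb.steady_state_spec(), 50, seed=9, geom=GEOM)
        b = mb.init_population(mb.steady_state_spec(), 50, seed=9, geom=GEOM)
        assert all(np.array_equal(p.position, q.position)
                   and p.radius == q.radius for p, q in zip(a, b))

    def test_population_volume_fraction_is_dilute(self):
        """2000 microtissues occupy ~0.1% of the 2-ml working volume."""
        pop = mb.init_population(mb.steady_state_spec(), 2000, seed=1,
                                 geom=GEOM)
        vol = sum(4 / 3 * math.pi * p.radius ** 3 for p in pop)
        assert 2e-4 < vol / GEOM.volume < 5e-3

    def test_no_initial_overlap(self):
        pop = mb.init_population(mb.steady_state_spec(), 200, seed=4,
                                 geom=GEOM)
        pos = np.array([p.position for p in pop])
        rad = np.array([p.radius for p in pop])
        d = np.linalg.norm(pos[:, None] - pos[None, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        assert np.all(d > (rad[:, None] + rad[None, :]) - 1e-12)

    def test_packing_failure_reports_achieved_n(self):
        tiny = mb.VesselGeometry(radius=0.4e-3, height=0.4e-3)
        with pytest.raises(PackingError) as err:
            mb.init_population(mb.steady_state_spec(), 2000, seed=0,
                               geom=tiny, max_retries=50)
        assert 0 <= err.value.achieved_n < 2000


class TestIntegrationOracles:
    def test_settling_converges_to_stokes_terminal_velocity(self):
        """In quiescent fluid a delta=0.05 particle reaches the analytic
        settling velocity within 1% after 5 response times."""
        q = mb.quiescent_field(GEOM)
        p = particle(pos=(3e-3, 0, 8e-3))
        susp = mb.Suspension([p], FLUID, GEOM, q, use_contacts=False)
        spec = mb.ParticleSpec(60e-6, FLUID.density * 1.05)
        t0 = mb.response_time(spec, FLUID)
        vt = mb.settling_velocity(spec, FLUID)
        dt = susp.max_dt()
        susp.step(dt, int(np.ceil(5 * t0 / dt)))
        assert susp.vel[0, 2] == pytest.approx(-vt, rel=0.01)

    def test_neutral_tracer_stays_on_solid_body_circle(self):
        """10 revolutions in rigid rotation keep a neutral particle on its
        circle to 0.5% (resolved time step)."""
        omega, r0 = 13.0, 3e-3
        sb = mb.solid_body_field(omega, GEOM)
        p = mb.ParticleState(0, 60e-6, FLUID.density,
                             np.array([r0, 0, 6e-3]),
                             np.array([0, omega * r0, 0]))
        susp = mb.Suspension([p], FLUID, GEOM, sb, use_contacts=False,
                             use_gravity=False)
        trajs = susp.run(10 * 2 * math.pi / omega, dt=8e-6, sample_every=500)
        radii = np.hypot(trajs[0].position[:, 0], trajs[0].position[:, 1])
        assert np.abs(radii - r0).max() / r0 < 0.005

    def test_rest_state_is_a_fixed_point(self):
        """Zero flow, zero gravity, zero contacts: nothing moves."""
        q = mb.quiescent_field(GEOM)
        p = particle(delta=0.0)
        susp = mb.Suspension([p], FLUID, GEOM, q, use_contacts=False,
                             use_gravity=False)
        x0 = susp.pos.copy()
        susp.step(susp.max_dt(), 100)
        assert np.array_equal(susp.pos, x0)
        assert not np.any(susp.vel)

    def test_time_step_bound_enforced(self):
        q = mb.quiescent_field(GEOM)
        susp = mb.Suspension([particle()], FLUID, GEOM, q)
        with pytest.raises(TimeStepError):
            susp.step(10 * susp.max_dt())

    def test_elastic_contact_conserves_energy(self):
        """Two particles bouncing without damping or fluid recover their
        kinetic energy to 1% after the bounce."""
        params = mb.ContactParams(normal_stiffness=1e-2, damping_ratio=0.0,
                                  wall_stiffness=1e-2)
        v0 = 1e-3
        a = mb.ParticleState(0, 60e-6, FLUID.density * 1.05,
                             np.array([-61e-6, 0, 5e-3]),
                             np.array([v0, 0, 0]))
        b = mb.ParticleState(1, 60e-6, FLUID.density * 1.05,
                             np.array([61e-6, 0, 5e-3]),
                             np.array([-v0, 0, 0]))
        susp = mb.Suspension([a, b], FLUID, GEOM, field=None, contact=params,
                             use_gravity=False)
        m = a.density * 4 / 3 * math.pi * a.radius ** 3
        e0 = 2 * 0.5 * m * v0 ** 2
        susp.step(2e-6, 2000)
        # separated again after the bounce
        gap = np.linalg.norm(susp.pos[0] - susp.pos[1])
        assert gap > 2 * a.radius
        e1 = 0.5 * m * float(np.sum(susp.vel ** 2))
        assert e1 == pytest.approx(e0, rel=0.01)
        # velocities reversed symmetrically
        assert susp.vel[0, 0] < 0 < susp.vel[1, 0]


class TestSimulate:
    def test_duration_zero_gives_single_sample(self, medium_field_small):
        cfg = mb.default_config("medium", n_particles=5, seed=0,
                                duration=0.0, grid=(32, 48))
        trajs = mb.simulate(cfg, medium_field_small)
        assert all(len(t.t) == 1 for t in trajs)

    def test_same_seed_identical_trajectories(self, medium_field_small):
        cfg = mb.default_config("medium", n_particles=10, seed=12,
                                duration=0.5, grid=(32, 48))
        t1 = mb.simulate(cfg, medium_field_small)
        t2 = mb.simulate(cfg, medium_field_small)
        for a, b in zip(t1, t2):
            assert np.array_equal(a.position, b.position)
            assert np.array_equal(a.velocity, b.velocity)

    def test_neutral_population_stays_suspended(self, medium_field_small):
        """At delta = 0 nearly all tracers keep circulating (mean speed
        above 1% of tip speed)."""
        cfg = mb.default_config("medium", n_particles=100, seed=2,
                                duration=20.0, sample_every=50,
                                grid=(32, 48)).with_delta(0.0)
        trajs = mb.simulate(cfg, medium_field_small)
        speeds = np.array([np.mean(np.linalg.norm(t.velocity, axis=1))
                           for t in trajs])
        assert np.mean(speeds > 0.01 * cfg.impeller.tip_speed) >= 0.95

    def test_containment(self, small_run):
        """No particle center leaves the vessel."""
        _, _, trajs = small_run
        for t in trajs:
            r = np.hypot(t.position[:, 0], t.position[:, 1])
            assert r.max() <= GEOM.radius * (1 + 1e-9)
            assert t.position[:, 2].min() >= -1e-12
            assert t.position[:, 2].max() <= GEOM.height * (1 + 1e-9)


class TestTracerOracles:
    def test_full_dynamics_matches_streamline_integration(
            self, medium_field_small):
        """Neutral microtissues are stream tracers: the full equation of
        motion reproduces 4th-order streamline integration to < 1% of the
        vessel radius over 10 s."""
        f = medium_field_small
        starts = [(2.5e-3, 0.0, 7e-3), (4.5e-3, 0.0, 3.5e-3),
                  (5.5e-3, 0.0, 8e-3)]
        duration, dt, sub = 10.0, 2.5e-6, 400
        parts = [mb.ParticleState(k, 60e-6, FLUID.density,
                                  np.array([r0 * math.cos(th), r0 *
                                            math.sin(th), z0]),
                                  mb.velocity_at(f, (r0, th, z0)))
                 for k, (r0, th, z0) in enumerate(starts)]
        susp = mb.Suspension(parts, FLUID, GEOM, f, use_contacts=False)
        trajs = susp.run(duration, dt=dt, sample_every=sub)

        def rhs(x):
            r = math.hypot(x[0], x[1])
            th = math.atan2(x[1], x[0])
            return mb.velocity_at(f, (min(r, GEOM.radius), th,
                                      min(max(x[2], 0.0), GEOM.height)))

        h = dt * sub   # one RK4 step per recorded sample
        for traj in trajs:
            x = traj.position[0].copy()
            err = 0.0
            for m in range(1, len(traj.t)):
                k1 = rhs(x)
                k2 = rhs(x + 0.5 * h * k1)
                k3 = rhs(x + 0.5 * h * k2)
                k4 = rhs(x + h * k3)
                x = x + (h / 6) * (k1 + 2 * k2 + 2 * k3 + k4)
                err = max(err, float(np.linalg.norm(x - traj.position[m])))
            assert err < 0.01 * GEOM.radius

    def test_time_rescaling_of_neutral_trajectories(self):
        """Stokes flow scales linearly with omega, so a neutral run at
        2*omega for half the time retraces the run at omega (matched
        non-dimensional step)."""
        i1 = mb.ImpellerSpec(angular_velocity=6.5)
        i2 = mb.ImpellerSpec(angular_velocity=13.0)
        f1 = mb.solve_flow(GEOM, FLUID, i1, resolution=(32, 48))
        f2 = mb.solve_flow(GEOM, FLUID, i2, resolution=(32, 48))
        starts = [(3e-3, 0.0, 7e-3), (5e-3, 0.0, 4e-3)]
        parts = lambda f: [
            mb.ParticleState(k, 60e-6, FLUID.density,
                             np.array([r0, 0.0, z0]),
                             mb.velocity_at(f, (r0, 0.0, z0)))
            for k, (r0, _, z0) in enumerate(starts)]
        dt = 2e-4
        s1 = mb.Suspension(parts(f1), FLUID, GEOM, f1, use_contacts=False)
        t1 = s1.run(8.0, dt=dt, sample_every=100)
        s2 = mb.Suspension(parts(f2), FLUID, GEOM, f2, use_contacts=False)
        t2 = s2.run(4.0, dt=dt / 2, sample_every=100)
        for a, b in zip(t1, t2):
            assert np.allclose(a.t, 2 * b.t)
            dev = np.linalg.norm(a.position - b.position, axis=1).max()
            assert dev < 0.01 * GEOM.radius


def test_trajectory_invariants_enforced():
    t = np.array([0.0, 1.0, 0.5])
    with pytest.raises(InvalidParameterError):
        mb.Trajectory(0, 60e-6, 1000.0, t, np.zeros((3, 3)),
                      np.zeros((3, 3)), np.zeros((3, 3)))
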