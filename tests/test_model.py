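"""Stoichiometric cortical-pulling model: unit oracles and trace properties."""

from functools import lru_cache

import numpy as np
import pytest

from spindlescale.model import (
    DEFAULT_PARAMS,
    STAGE_TABLE,
    ChromosomeProgram,
    SimulationParams,
    SimulationState,
    SurfaceField,
    imposed_chromosome_separation,
    impingement_rate,
    motor_force,
    simulate_stage,
    sphere_patches,
    step_positions,
    step_surface_field,
    surface_field_steady_state,
)

PARAMS = SimulationParams(lam=0.164)


@lru_cache(maxsize=None)
def stage_trace(stage, dt=0.1, n_patches=500, lam=None, record=False):
    return simulate_stage(
        STAGE_TABLE[stage], duration=300.0, dt=dt, n_patches=n_patches,
        lam=lam, record_states=record, record_every=500,
    )


class TestSpherePatches:
    @pytest.mark.parametrize("n,R", [(500, 14.0), (2000, 7.3), (123, 23.0)])
    def test_weights_sum_to_sphere_area(self, n, R):
        pts, areas = sphere_patches(n, R)
        assert np.sum(areas) == pytest.approx(4 * np.pi * R**2, rel=1e-12)
        assert np.allclose(np.linalg.norm(pts, axis=1), R, atol=1e-10)

    def test_first_moment_vanishes(self):
        """Quadrature of the position vector over the sphere is zero."""
        pts, areas = sphere_patches(800, 10.0)
        assert np.linalg.norm(areas @ pts) < 1e-9 * np.sum(areas)

    def test_quadratic_moment_oracle(self):
        """Integral of z^2 over the sphere is (4/3) pi R^4."""
        R = 5.0
        pts, areas = sphere_patches(600, R)
        got = np.sum(areas * pts[:, 2] ** 2)
        assert got == pytest.approx(4 * np.pi * R**4 / 3, rel=1e-10)


class TestImpingementRate:
    def test_closed_form_oracle(self):
        """Omega = N_T lam r^2/(4 d^2) exp(-lam d/V_g) at d = 5 um."""
        om = impingement_rate([0, 0, 0], [5.0, 0, 0], PARAMS)
        want = 5000 * 0.164 * 1.5**2 / (4 * 25.0) * np.exp(-0.164 * 5.0 / 1.0)
        assert om == pytest.approx(want, rel=1e-12)

    def test_vectorized_matches_scalar(self):
        rng = np.random.default_rng(0)
        patches = rng.normal(0, 5, (20, 3)) + np.array([10.0, 0, 0])
        om = impingement_rate([0, 0, 0], patches, PARAMS)
        for i, p in enumerate(patches):
            assert om[i] == pytest.approx(impingement_rate([0, 0, 0], p, PARAMS), rel=1e-14)

    def test_monotone_decreasing_in_distance(self):
        d = np.linspace(1.0, 40.0, 100)
        om = impingement_rate([0, 0, 0], np.column_stack([d, 0 * d, 0 * d]), PARAMS)
        assert np.all(np.diff(om) < 0)

    def test_coincident_patch_rejected(self):
        with pytest.raises(ValueError):
            impingement_rate([1.0, 0, 0], [1.0, 0, 0], PARAMS)


def make_field(n=200, R=10.0, p1=0.0, p2=0.0):
    pts, areas = sphere_patches(n, R)
    return SurfaceField(
        pts, areas, np.full(len(pts), p1), np.full(len(pts), p2), R
    )


class TestSurfaceField:
    def test_steady_state_is_fixed_point_of_exponential_step(self):
        f = make_field()
        om1 = impingement_rate([3.0, 0, 0], f.points, PARAMS)
        om2 = impingement_rate([-3.0, 0, 0], f.points, PARAMS)
        P1, P2 = surface_field_steady_state(om1, om2, PARAMS.kappa)
        f.P1, f.P2 = np.asarray(P1), np.asarray(P2)
        out = step_surface_field(f, om1, om2, PARAMS.kappa, dt=5.0, scheme="exponential")
        assert np.allclose(out.P1, P1, atol=1e-12)
        assert np.allclose(out.P2, P2, atol=1e-12)

    def test_euler_converges_to_steady_state(self):
        f = make_field()
        om1 = impingement_rate([3.0, 0, 0], f.points, PARAMS)
        om2 = impingement_rate([-3.0, 0, 0], f.points, PARAMS)
        for _ in range(8000):
            f = step_surface_field(f, om1, om2, PARAMS.kappa, dt=0.05, scheme="euler")
        P1, P2 = surface_field_steady_state(om1, om2, PARAMS.kappa)
        assert np.allclose(f.P1, P1, atol=1e-6)
        assert np.allclose(f.P2, P2, atol=1e-6)
        assert f.n_clipped == 0

    def test_exponential_matches_euler_when_stable(self):
        f_e = make_field()
        f_x = make_field()
        om1 = impingement_rate([4.0, 0, 0], f_e.points, PARAMS)
        om2 = impingement_rate([-4.0, 0, 0], f_e.points, PARAMS)
        for _ in range(2000):
            f_e = step_surface_field(f_e, om1, om2, PARAMS.kappa, dt=0.01, scheme="euler")
            f_x = step_surface_field(f_x, om1, om2, PARAMS.kappa, dt=0.01, scheme="exponential")
        assert np.allclose(f_e.P1, f_x.P1, atol=5e-4)

    def test_zero_impingement_decays_exponentially(self):
        """With Omega = 0 the field relaxes as exp(-kappa t) exactly."""
        f = make_field(p1=0.8, p2=0.1)
        z = np.zeros(len(f.points))
        out = step_surface_field(f, z, z, PARAMS.kappa, dt=7.0, scheme="exponential")
        assert np.allclose(out.P1, 0.8 * np.exp(-PARAMS.kappa * 7.0), atol=1e-13)
        assert np.allclose(out.P2, 0.1 * np.exp(-PARAMS.kappa * 7.0), atol=1e-13)

    def test_aster_swap_symmetry(self):
        f = make_field()
        om1 = impingement_rate([3.0, 0, 0], f.points, PARAMS)
        om2 = impingement_rate([-2.0, 1.0, 0], f.points, PARAMS)
        a = step_surface_field(f.copy(), om1, om2, PARAMS.kappa, 0.5, "exponential")
        b = step_surface_field(f.copy(), om2, om1, PARAMS.kappa, 0.5, "exponential")
        assert np.allclose(a.P1, b.P2, atol=1e-15)
        assert np.allclose(a.P2, b.P1, atol=1e-15)

    def test_probability_bounds_preserved(self):
        f = make_field(p1=0.5, p2=0.5)
        om1 = impingement_rate([8.0, 0, 0], f.points, PARAMS)  # near the cortex: stiff
        om2 = impingement_rate([-8.0, 0, 0], f.points, PARAMS)
        for _ in range(50):
            f = step_surface_field(f, om1, om2, PARAMS.kappa, dt=1.0, scheme="exponential")
            assert np.all(f.P1 >= 0) and np.all(f.P2 >= 0)
            assert np.all(f.P1 + f.P2 <= 1.0 + 1e-12)

    def test_euler_rejects_unstable_step(self):
        f = make_field()
        om1 = impingement_rate([9.5, 0, 0], f.points, PARAMS)
        with pytest.raises(ValueError, match="stability"):
            step_surface_field(f, om1, om1, PARAMS.kappa, dt=5.0, scheme="euler")

    def test_unknown_scheme_rejected(self):
        f = make_field()
        with pytest.raises(ValueError, match="scheme"):
            step_surface_field(f, 0.0, 0.0, PARAMS.kappa, 0.1, "rk4")


class TestMotorForce:
    def test_centred_pole_uniform_field_zero_force(self):
        """Symmetric configuration: the quadrature must not invent a force."""
        f = make_field(n=500, p1=0.3)
        F = motor_force(f, np.zeros(3), f.P1, PARAMS)
        scale = PARAMS.rho * PARAMS.f0 * np.sum(f.areas)
        assert np.linalg.norm(F) < 1e-10 * scale

    def test_single_patch_pulls_toward_it(self):
        f = make_field(n=300)
        P = np.zeros(len(f.points))
        P[7] = 0.5
        pole = np.array([2.0, 1.0, -0.5])
        F = motor_force(f, pole, P, PARAMS)
        xi = (f.points[7] - pole) / np.linalg.norm(f.points[7] - pole)
        want = PARAMS.rho * PARAMS.f0 * 0.5 * f.areas[7] * xi
        assert np.allclose(F, want, atol=1e-12)

    def test_quadrature_refinement_converged(self):
        """The 500-patch force matches an 8000-patch reference."""
        pole = np.array([4.0, 0.0, 0.0])
        forces = {}
        for n in (500, 8000):
            pts, areas = sphere_patches(n, 14.0)
            om1 = impingement_rate(pole, pts, PARAMS)
            om2 = impingement_rate(-pole, pts, PARAMS)
            P1, _ = surface_field_steady_state(om1, om2, PARAMS.kappa)
            f = SurfaceField(pts, areas, np.asarray(P1), np.zeros(len(pts)), 14.0)
            forces[n] = motor_force(f, pole, f.P1, PARAMS)
        rel = np.linalg.norm(forces[500] - forces[8000]) / np.linalg.norm(forces[8000])
        assert rel < 1e-10

    def test_outward_pole_pulled_outward(self):
        """A pole displaced toward the cortex with its steady field is pulled
        further outward (the basis of cortical pulling)."""
        pole = np.array([4.0, 0.0, 0.0])
        pts, areas = sphere_patches(1000, 14.0)
        om1 = impingement_rate(pole, pts, PARAMS)
        om2 = impingement_rate(-pole, pts, PARAMS)
        P1, _ = surface_field_steady_state(om1, om2, PARAMS.kappa)
        f = SurfaceField(pts, areas, np.asarray(P1), np.zeros(len(pts)), 14.0)
        F = motor_force(f, pole, f.P1, PARAMS)
        assert F[0] > 0


class TestChromosomeProgram:
    def test_reference_values(self):
        prog = ChromosomeProgram()
        assert imposed_chromosome_separation(0.0, prog) == 0.0
        assert imposed_chromosome_separation(29.0, prog) == pytest.approx(
            6.2 * (1 - np.exp(-1)), rel=1e-12
        )
        assert imposed_chromosome_separation(1e6, prog) == pytest.approx(6.2, rel=1e-9)

    def test_vectorized(self):
        t = np.linspace(0, 120, 13)
        out = imposed_chromosome_separation(t, ChromosomeProgram())
        assert np.allclose(out, 6.2 * (1 - np.exp(-t / 29.0)), atol=1e-14)
        assert np.all(np.diff(out) > 0)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            imposed_chromosome_separation(-1.0, ChromosomeProgram())


def make_state(d0=9.0):
    axis = np.array([1.0, 0.0, 0.0])
    x1, x2 = 0.5 * d0 * axis, -0.5 * d0 * axis
    mid = np.zeros(3)
    return SimulationState(x1=x1, x2=x2, c1=mid.copy(), c2=mid.copy(), s_hat=axis)


class TestStepPositions:
    def test_velocity_matches_linear_solve_oracle(self):
        """Pole displacement equals dt * v with (eta I + nu s s^T) v = F + nu cdot_par s."""
        rng = np.random.default_rng(3)
        state = make_state()
        F1, F2 = rng.normal(0, 40, 3), rng.normal(0, 40, 3)
        cd1, cd2 = 0.11, -0.11
        dt = 0.05
        out = step_positions(state, F1, F2, DEFAULT_PARAMS, ChromosomeProgram(), dt,
                             R=14.0, cdot1_par=cd1, cdot2_par=cd2)
        s = state.s_hat
        M = DEFAULT_PARAMS.eta * np.eye(3) + DEFAULT_PARAMS.nu * np.outer(s, s)
        for x_old, x_new, F, cd in ((state.x1, out.x1, F1, cd1), (state.x2, out.x2, F2, cd2)):
            v = np.linalg.solve(M, F + DEFAULT_PARAMS.nu * cd * s)
            assert np.allclose(x_new, x_old + dt * v, atol=1e-12)

    def test_zero_force_leaves_poles_fixed(self):
        state = make_state()
        out = step_positions(state, np.zeros(3), np.zeros(3), DEFAULT_PARAMS,
                             ChromosomeProgram(), 0.1, R=14.0, cdot1_par=0.0, cdot2_par=0.0)
        assert np.allclose(out.x1, state.x1, atol=1e-15)
        assert np.allclose(out.x2, state.x2, atol=1e-15)

    def test_plates_straddle_midpoint_by_program(self):
        state = make_state()
        prog = ChromosomeProgram()
        dt = 2.0
        out = step_positions(state, np.zeros(3), np.zeros(3), DEFAULT_PARAMS, prog,
                             dt, R=14.0, cdot1_par=0.0, cdot2_par=0.0)
        dc = imposed_chromosome_separation(dt, prog)
        assert np.linalg.norm(out.c1 - out.c2) == pytest.approx(dc, abs=1e-12)
        assert np.allclose(0.5 * (out.c1 + out.c2), 0.5 * (out.x1 + out.x2), atol=1e-12)

    def test_pole_clipped_to_sphere(self):
        state = make_state(d0=9.0)
        big = np.array([1e6, 0.0, 0.0])
        out = step_positions(state, big, -big, DEFAULT_PARAMS, ChromosomeProgram(),
                             1.0, R=5.0, cdot1_par=0.0, cdot2_par=0.0)
        assert out.clipped
        assert np.linalg.norm(out.x1) <= 5.0
        assert np.linalg.norm(out.x2) <= 5.0

    def test_bad_dt_rejected(self):
        with pytest.raises(ValueError):
            step_positions(make_state(), np.zeros(3), np.zeros(3), DEFAULT_PARAMS,
                           ChromosomeProgram(), 0.0, R=14.0, cdot1_par=0.0, cdot2_par=0.0)


class TestSimulateStage:
    def test_initial_conditions(self):
        tr = stage_trace(8)
        assert tr.times[0] == 0.0
        assert tr.d_pp[0] == pytest.approx(STAGE_TABLE[8].initial_pole_distance)
        assert tr.d_cc[0] == 0.0

    def test_chromosome_trace_equals_program_exactly(self):
        tr = stage_trace(8)
        want = imposed_chromosome_separation(tr.times, ChromosomeProgram())
        assert np.allclose(tr.d_cc, want, atol=1e-12)

    def test_two_cell_elongates_and_plateaus(self):
        tr = stage_trace(2)
        assert np.all(np.diff(tr.d_pp) > -1e-9)  # monotone elongation
        late = tr.d_pp[tr.times >= 250]
        assert (late.max() - late.min()) < 0.15  # plateau over the last 50 s

    def test_no_lateral_drift(self):
        """On-axis start stays on axis to better than 1e-6 R."""
        tr = stage_trace(8, record=True)
        state = tr.states[-1][0]
        off = np.abs([state.x1[1], state.x1[2], state.x2[1], state.x2[2]])
        assert np.max(off) < 1e-6 * STAGE_TABLE[8].R

    def test_mirror_symmetry(self):
        tr = stage_trace(8, record=True)
        state = tr.states[-1][0]
        assert np.linalg.norm(state.x1 + state.x2) < 1e-9

    def test_field_probabilities_bounded(self):
        tr = stage_trace(8, record=True)
        f = tr.states[-1][1]
        assert np.all(f.P1 >= 0) and np.all(f.P2 >= 0)
        assert np.all(f.P1 + f.P2 <= 1.0 + 1e-9)

    def test_higher_catastrophe_rate_shortens_spindle(self):
        base = stage_trace(8)
        fast = stage_trace(8, lam=1.64)
        assert fast.d_pp[-1] < base.d_pp[-1] - 1.0

    def test_final_length_monotone_across_stages(self):
        finals = [stage_trace(s).d_pp[-1] for s in sorted(STAGE_TABLE)]
        assert np.all(np.diff(finals) < 0)

    def test_time_step_convergence(self):
        a = stage_trace(8, dt=0.1).d_pp[-1]
        b = stage_trace(8, dt=0.05).d_pp[-1]
        assert abs(a - b) / b < 1e-6

    def test_patch_count_convergence(self):
        a = stage_trace(8, n_patches=500).d_pp[-1]
        b = stage_trace(8, n_patches=2000).d_pp[-1]
        assert abs(a - b) / b < 1e-6

    def test_euler_and_exponential_schemes_agree_when_stable(self):
        cfg = STAGE_TABLE[2]  # large cell: Omega small enough for Euler at dt=0.1
        a = simulate_stage(cfg, duration=60.0, dt=0.1, n_patches=500, field_scheme="euler")
        b = simulate_stage(cfg, duration=60.0, dt=0.1, n_patches=500, field_scheme="exponential")
        assert abs(a.d_pp[-1] - b.d_pp[-1]) < 0.01

    def test_euler_rejects_stiff_small_cell(self):
        # the field is stiffest once the poles approach the cortex, so the
        # violation surfaces mid-run rather than at the pre-check
        with pytest.raises(ValueError, match="stability"):
            simulate_stage(STAGE_TABLE[64], duration=300.0, dt=0.1, n_patches=500,
                           field_scheme="euler")

    def test_stage_tuned_rates_preserve_proportional_elongation(self):
        """Relative elongation (final/initial) is nearly stage-invariant with
        the stage-tuned catastrophe rates, but spans > 2x with a constant
        rate: matching the scaling data requires lambda to vary with size."""
        tuned = np.array(
            [stage_trace(s).d_pp[-1] / STAGE_TABLE[s].initial_pole_distance
             for s in sorted(STAGE_TABLE)]
        )
        const = np.array(
            [stage_trace(s, lam=0.3).d_pp[-1] / STAGE_TABLE[s].initial_pole_distance
             for s in sorted(STAGE_TABLE)]
        )
        assert tuned.max() / tuned.min() < 1.3
        assert const.max() / const.min() > 2.0
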