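"""Fixed-step schemes: single-step oracles, convergence orders,
equilibrium preservation, divergence handling and amplification factors."""

import math

import numpy as np
import pytest

from dcmodel import (
    InsufficientHistoryError,
    ModelParameters,
    State,
    amplification,
    derived_constants,
    equilibrium,
    initial_conditions,
    integrate,
    propagate,
    rhs,
    step_abm4,
    step_explicit_euler,
    step_heun,
    step_implicit_euler,
    step_rk4,
)

NUMERIC = ("explicit_euler", "implicit_euler", "heun", "rk4", "abm4")


class TestSingleSteps:
    @pytest.mark.parametrize("method", NUMERIC)
    def test_equilibrium_held_fixed_for_100_steps(self, params, method):
        eq = equilibrium(params)
        s0 = State(0.0, eq.C_star, eq.N_star)
        traj = integrate(method, s0, params, 1.0, 100.0)
        last = traj.states[-1]
        assert last.C == pytest.approx(eq.C_star, rel=1e-12)
        assert last.N == pytest.approx(eq.N_star, rel=1e-12)

    def test_explicit_euler_single_step_arithmetic(self, params, anchor):
        s = anchor.state
        dC, dN = rhs(s, params)
        out = step_explicit_euler(s, 1.0, params)
        assert out.C == pytest.approx(s.C + dC, rel=1e-12)
        assert out.N == pytest.approx(s.N + dN, rel=1e-12)
        assert s.C - out.C == pytest.approx(53_267.77, abs=0.5)  # C drops by ~5.3e4

    def test_explicit_euler_consistency_as_dt_vanishes(self, params, anchor):
        s = anchor.state
        dC, _ = rhs(s, params)
        for dt in (1e-3, 1e-6):
            out = step_explicit_euler(s, dt, params)
            assert (out.C - s.C) / dt == pytest.approx(dC, rel=1e-6)

    def test_implicit_euler_scalar_reduction(self):
        # lambda = 0, I = 0: C decouples and the step has the closed form
        p = ModelParameters(lambda_=0.0, delta=0.2, mu=0.1, gamma=0.3, nu=0.0, incidence=0.0)
        s = State(0.0, 1000.0, 2000.0)
        out = step_implicit_euler(s, 0.5, p)
        assert out.C == pytest.approx(1000.0 / (1.0 + 0.5 * p.theta), rel=1e-12)

    def test_implicit_euler_matches_fixed_point_iteration_oracle(self, params, anchor):
        # brute-force iteration of the coupled update pair
        s = anchor.state
        dt = 1.0
        lam, theta, mu = params.lambda_, params.theta, params.mu
        nd, I = params.nu + params.delta, params.incidence
        C, N = s.C, s.N
        for _ in range(200):
            C = (dt * (I + lam * N) + s.C) / (1.0 + dt * (lam + theta))
            N = (dt * (2 * I - C * nd) + s.N) / (1.0 + dt * mu)
        out = step_implicit_euler(s, dt, params)
        assert out.C == pytest.approx(C, rel=1e-10)
        assert out.N == pytest.approx(N, rel=1e-10)

    def test_implicit_euler_gauss_seidel_variant_differs(self, params, anchor):
        exact = step_implicit_euler(anchor.state, 1.0, params)
        sweep = step_implicit_euler(anchor.state, 1.0, params, gauss_seidel=True)
        assert sweep.C != exact.C  # one sweep is not the coupled solve
        assert sweep.C == pytest.approx(exact.C, rel=1e-3)

    def test_heun_matches_two_stage_arithmetic_oracle(self, params, anchor):
        s = anchor.state
        dt = 1.0
        f0 = np.array(rhs(s, params))
        pred = State(s.t + dt, s.C + dt * f0[0], s.N + dt * f0[1])
        f1 = np.array(rhs(pred, params))
        expect = np.array([s.C, s.N]) + dt / 2 * (f0 + f1)
        out = step_heun(s, dt, params)
        assert out.C == pytest.approx(expect[0], rel=1e-12)
        assert out.N == pytest.approx(expect[1], rel=1e-12)

    def test_rk4_pure_decay_stability_polynomial(self):
        # lambda = 0, I = 0: the C update reduces to the RK4 polynomial in theta*dt
        p = ModelParameters(lambda_=0.0, delta=0.2, mu=0.0, gamma=0.3, nu=0.0, incidence=0.0)
        x = p.theta * 1.0
        poly = 1 - x + x**2 / 2 - x**3 / 6 + x**4 / 24
        out = step_rk4(State(0.0, 1000.0, 0.0), 1.0, p)
        assert out.C == pytest.approx(1000.0 * poly, rel=1e-12)

    def test_abm4_requires_four_states(self, params, anchor):
        with pytest.raises(InsufficientHistoryError):
            step_abm4([anchor.state] * 3, 1.0, params)

    def test_abm4_constant_history_stays_constant(self, params):
        eq = equilibrium(params)
        hist = [State(float(t), eq.C_star, eq.N_star) for t in range(4)]
        out = step_abm4(hist, 1.0, params)
        assert out.C == pytest.approx(eq.C_star, rel=1e-12)
        assert out.N == pytest.approx(eq.N_star, rel=1e-12)


class TestIntegrate:
    def test_zero_span_single_state(self, params, anchor):
        traj = integrate("rk4", anchor.state, params, 1.0, anchor.state.t)
        assert len(traj.states) == 1 and traj.states[0] is anchor.state

    def test_off_grid_horizon_rejected(self, params, anchor):
        with pytest.raises(ValueError):
            integrate("rk4", anchor.state, params, 1.0, anchor.state.t + 4.5)

    def test_analytic_method_delegates_to_propagator(self, params, anchor):
        traj = integrate("analytic", anchor.state, params, 5.0, 20.0)
        for s in traj.states[1:]:
            pr = propagate(anchor.state, s.t - anchor.state.t, params)
            assert s.C == pr.C and s.N == pr.N

    def test_uniform_grid_spacing(self, params, anchor):
        traj = integrate("heun", anchor.state, params, 0.25, anchor.state.t + 5.0)
        dts = np.diff(traj.times)
        assert np.allclose(dts, 0.25, rtol=0, atol=1e-12)
        assert len(traj.states) == 21

    def test_explicit_euler_large_step_diverges(self, params, anchor):
        traj = integrate("explicit_euler", anchor.state, params, 3.0, anchor.state.t + 300.0)
        assert traj.diverged and traj.diverged_at is not None
        assert len(traj.states) < 101  # truncated at first divergent state

    def test_explicit_euler_dt_1_5_oscillates_without_diverging(self, params, anchor):
        traj = integrate("explicit_euler", anchor.state, params, 1.5, anchor.state.t + 15.0)
        assert not traj.diverged
        assert not amplification("explicit_euler", params, 1.5).stable

    def test_linearity_under_problem_scaling(self, params, anchor):
        k = 3.0
        scaled = params.replace(incidence=k * params.incidence)
        s0 = anchor.state
        s0k = State(s0.t, k * s0.C, k * s0.N)
        for method in NUMERIC:
            a = integrate(method, s0, params, 1.0, s0.t + 10.0).states[-1]
            b = integrate(method, s0k, scaled, 1.0, s0.t + 10.0).states[-1]
            assert b.C == pytest.approx(k * a.C, rel=1e-12)
            assert b.N == pytest.approx(k * a.N, rel=1e-12)


class TestAccuracy:
    @pytest.mark.parametrize(
        "method,dts,expected,tol",
        [
            ("explicit_euler", (0.5, 0.25), 1.0, 0.1),
            ("implicit_euler", (0.5, 0.25), 1.0, 0.1),
            ("heun", (0.5, 0.25), 2.0, 0.1),
            ("rk4", (1.0, 0.5), 4.0, 0.3),
            ("abm4", (0.5, 0.25), 4.0, 0.5),
        ],
    )
    def test_empirical_convergence_order(self, end_error, method, dts, expected, tol):
        order = math.log2(end_error(method, dts[0]) / end_error(method, dts[1]))
        assert order == pytest.approx(expected, abs=tol)

    def test_error_ranking_at_unit_step(self, end_error):
        errs = {m: end_error(m, 1.0) for m in NUMERIC}
        assert errs["rk4"] < errs["abm4"] < errs["heun"]
        assert errs["heun"] < min(errs["implicit_euler"], errs["explicit_euler"])

    @pytest.mark.parametrize("method", NUMERIC)
    def test_halving_dt_reduces_end_error(self, end_error, method):
        assert end_error(method, 0.5) < end_error(method, 1.0)

    def test_abm4_tracks_fine_rk4_truth(self, params):
        s0 = initial_conditions(params, 500.0, 500.0)
        abm = integrate("abm4", s0, params, 0.5, 20.0).states[-1]
        fine = integrate("rk4", s0, params, 0.001, 20.0).states[-1]
        assert abm.C == pytest.approx(fine.C, rel=1e-6)
        assert abm.N == pytest.approx(fine.N, rel=1e-6)


class TestAmplification:
    def test_explicit_euler_threshold_at_fast_mode(self, params):
        k = derived_constants(params)
        dt_crit = 2.0 / k.eta2
        assert amplification("explicit_euler", params, 0.999 * dt_crit).stable
        assert not amplification("explicit_euler", params, 1.001 * dt_crit).stable
        assert dt_crit == pytest.approx(1.4197, abs=1e-3)

    @pytest.mark.parametrize("dt", (0.1, 1.0, 10.0, 100.0))
    def test_implicit_euler_unconditionally_stable(self, params, dt):
        report = amplification("implicit_euler", params, dt)
        assert report.stable
        assert all(0 < f < 1 for f in report.factors)

    @pytest.mark.parametrize("method", NUMERIC + ("analytic",))
    def test_factors_approach_one_as_dt_vanishes(self, params, method):
        report = amplification(method, params, 1e-8)
        assert all(abs(f - 1.0) < 1e-6 for f in report.factors)

    def test_analytic_factors_are_exact_exponentials(self, params):
        k = derived_constants(params)
        report = amplification("analytic", params, 0.7)
        assert report.factors[0] == pytest.approx(math.exp(-0.7 * k.eta1), rel=1e-12)
        assert report.factors[1] == pytest.approx(math.exp(-0.7 * k.eta2), rel=1e-12)

    def test_one_step_factors_match_observed_mode_decay(self, params):
        # integrate a pure slow-mode perturbation one step and compare with
        # the predicted growth factor
        eq = equilibrium(params)
        A = params.system_matrix()
        w, V = np.linalg.eig(A)
        slow = int(np.argmax(w.real))  # eigenvalue closest to zero
        v = V[:, slow].real
        s0 = State(0.0, eq.C_star + 1e4 * v[0], eq.N_star + 1e4 * v[1])
        for method, step in [("explicit_euler", step_explicit_euler), ("heun", step_heun), ("rk4", step_rk4)]:
            out = step(s0, 1.0, params)
            observed = (out.C - eq.C_star) / (s0.C - eq.C_star)
            predicted = amplification(method, params, 1.0).factors[0]
            assert observed == pytest.approx(predicted, rel=1e-6)
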