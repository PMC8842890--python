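"""Physics, force and score tests for the virtual pendulum."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pendulearn.exceptions import InvalidStateError
from pendulearn.pendulum import (PendulumParams, PendulumState, PendulumTrace,
                                 PivotTrajectory, compute_score,
                                 decompose_rod_force, rod_force,
                                 simulate_block, step_dynamics, wrap_angle)


class TestStepDynamics:
    def test_stable_equilibrium_is_fixed_point(self, params):
        s = PendulumState(0.0, 0.0, 0.0)
        out = step_dynamics(s, (0.0, 0.0), params, 0.01)
        assert out.theta == 0.0 and out.theta_dot == 0.0

    def test_inverted_equilibrium_is_fixed_point(self, params):
        s = PendulumState(0.0, math.pi, 0.0)
        out = step_dynamics(s, (0.0, 0.0), params, 0.01)
        assert out.theta == pytest.approx(math.pi, abs=1e-12)
        assert out.theta_dot == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("rod_length, expected_omega",
                             [(0.35, 2.647), (0.25, 3.132)])
    def test_small_angle_frequency(self, rod_length, expected_omega):
        # undamped small oscillation must match sqrt(g/l) within 0.5%
        p = PendulumParams(l=rod_length, c=0.0)
        pivot = PivotTrajectory.stationary(20.0, 1000.0)
        trace = simulate_block(pivot, PendulumState(0.0, 0.01, 0.0), p)
        crossings = np.flatnonzero((trace.theta[:-1] < 0)
                                   & (trace.theta[1:] >= 0))
        period = np.mean(np.diff(pivot.t[crossings]))
        omega = 2 * math.pi / period
        assert omega == pytest.approx(p.natural_frequency, rel=5e-3)
        assert omega == pytest.approx(expected_omega, rel=5e-3)

    def test_rejects_bad_inputs(self, params):
        s = PendulumState(0.0, 0.1, 0.0)
        with pytest.raises(ValueError):
            step_dynamics(s, (0.0, 0.0), params, 0.0)
        with pytest.raises(InvalidStateError):
            step_dynamics(PendulumState(0.0, math.nan, 0.0), (0.0, 0.0),
                          params, 0.01)

    def test_fourth_order_convergence(self, params):
        # halving dt shrinks the error ~16x on a smooth trajectory
        def run(dt):
            s = PendulumState(0.0, 1.0, 0.0)
            for _ in range(int(round(1.0 / dt))):
                s = step_dynamics(s, (0.5, 0.2), params, dt)
            return s.theta

        ref = run(1.0 / 8000)
        err_coarse = abs(run(1.0 / 250) - ref)
        err_fine = abs(run(1.0 / 500) - ref)
        assert err_coarse / err_fine == pytest.approx(16.0, rel=0.25)


class TestSimulateBlock:
    def test_damped_free_response_decays(self, params):
        pivot = PivotTrajectory.stationary(30.0, 600.0)
        trace = simulate_block(pivot, PendulumState(0.0, 0.2, 0.0), params)
        assert abs(trace.theta[-1]) < abs(trace.theta[0])

    def test_energy_conserved_without_damping(self):
        p = PendulumParams(c=0.0)
        pivot = PivotTrajectory.stationary(30.0, 3000.0)
        trace = simulate_block(pivot, PendulumState(0.0, 0.3, 0.0), p)
        energy = p.energy(trace.theta, trace.theta_dot)
        assert np.max(np.abs(energy - energy[0])) / energy[0] < 1e-6

    def test_energy_monotone_with_damping(self, params):
        pivot = PivotTrajectory.stationary(10.0, 1000.0)
        trace = simulate_block(pivot, PendulumState(0.0, 0.5, 0.0), params)
        energy = params.energy(trace.theta, trace.theta_dot)
        assert np.all(np.diff(energy) <= 1e-9)

    def test_resonant_pumping_grows_amplitude(self):
        # driving the pivot at the natural frequency pumps the swing
        p = PendulumParams(c=0.0)
        fs = 1000.0
        t = np.arange(int(8 * fs) + 1) / fs
        amp = 0.005
        w = p.natural_frequency
        y = amp * np.sin(w * t)
        pivot = PivotTrajectory(t, y, 0 * t, amp * w * np.cos(w * t), 0 * t,
                                -amp * w**2 * np.sin(w * t), 0 * t)
        trace = simulate_block(pivot, PendulumState(0.0, 0.001, 0.0), p)
        half = len(trace) // 2
        assert np.max(np.abs(trace.theta[half:])) > 2 * np.max(
            np.abs(trace.theta[:half]))

    def test_substepping_matches_fine_sampling(self, params):
        # coarse pivot sampling with internal sub-steps stays close to a
        # fine-step reference on a smooth drive
        fs = 100.0
        t = np.arange(int(2 * fs) + 1) / fs
        y_dd = 2.0 * np.sin(2 * np.pi * 1.0 * t)
        pivot = PivotTrajectory(t, 0 * t, 0 * t, 0 * t, 0 * t, y_dd, 0 * t)
        init = PendulumState(0.0, 0.1, 0.0)
        coarse = simulate_block(pivot, init, params, max_step=1 / 3000)
        single = simulate_block(pivot, init, params, max_step=1 / 100)
        assert coarse.theta[-1] == pytest.approx(single.theta[-1], abs=1e-5)

    def test_empty_trajectory_rejected(self, params):
        with pytest.raises(ValueError):
            PivotTrajectory.stationary(0.0, 100.0)


class TestRodForce:
    def test_horizontal_rod_at_rest_is_zero(self, params):
        assert rod_force(PendulumState(0.0, math.pi / 2, 0.0), (0.0, 0.0),
                         params) == pytest.approx(0.0, abs=1e-12)

    def test_static_hang_equals_weight(self, params):
        f = rod_force(PendulumState(0.0, 0.0, 0.0), (0.0, 0.0), params)
        assert f == pytest.approx(2.5 * 2.4525, rel=1e-9)

    def test_centrifugal_term(self, params):
        f = rod_force(PendulumState(0.0, 0.0, 2.0), (0.0, 0.0), params)
        assert f == pytest.approx(2.5 * (4 * 0.35 + 2.4525), rel=1e-9)

    @settings(derandomize=True, max_examples=50)
    @given(f=st.floats(-50, 50), theta=st.floats(-10, 10))
    def test_decomposition_preserves_magnitude(self, f, theta):
        f_y, f_z = decompose_rod_force(f, theta)
        assert math.hypot(f_y, f_z) == pytest.approx(abs(f), abs=1e-9)

    def test_decomposition_geometry(self):
        f_y, f_z = decompose_rod_force(6.131, 0.0)
        assert (f_y, f_z) == pytest.approx((0.0, -6.131), abs=1e-9)
        f_y, f_z = decompose_rod_force(5.0, math.pi)
        assert (f_y, f_z) == pytest.approx((0.0, 5.0), abs=1e-9)


def _hold_trace(segments, fs=1000.0):
    """Piecewise-constant theta trace from (duration, theta) segments."""
    theta = np.concatenate([np.full(int(round(d * fs)), th)
                            for d, th in segments])
    t = np.arange(theta.size) / fs
    return PendulumTrace(t, theta, np.zeros_like(theta))


class TestScore:
    def test_never_inverted_scores_zero(self, params):
        trace = _hold_trace([(3.0, 0.0)])
        res = compute_score(trace, params)
        assert res.score == 0.0 and res.inversion_intervals == ()

    def test_one_second_perfect_hold(self, params):
        trace = _hold_trace([(1.0, 0.0), (1.0 + 1 / 1000, math.pi),
                             (1.0, 0.0)])
        res = compute_score(trace, params)
        assert res.score == pytest.approx(19 * math.pi / 6, rel=1e-3)
        assert len(res.inversion_intervals) == 1

    def test_score_retained_across_drop(self, params):
        trace = _hold_trace([(0.5, 0.0), (1.0 + 1 / 1000, math.pi),
                             (1.0, 0.0), (1.0 + 1 / 1000, math.pi),
                             (0.5, 0.0)])
        res = compute_score(trace, params)
        assert res.score == pytest.approx(2 * 19 * math.pi / 6, rel=1e-3)
        assert len(res.inversion_intervals) == 2

    def test_speed_condition_gates_score(self, params):
        n = 2001
        t = np.arange(n) / 1000.0
        theta = np.full(n, math.pi)
        fast = np.full(n, 1.5 * params.speed_tol)
        assert compute_score(PendulumTrace(t, theta, fast), params).score == 0.0

    def test_wrapped_angle_distance_used(self, params):
        # -pi is the same inverted pose as +pi
        trace = _hold_trace([(1.0, -math.pi)])
        assert compute_score(trace, params).score > 0

    def test_score_rate_bound(self, params, rng):
        # random band-limited trajectories never beat k*angle_tol per second
        duration, fs = 10.0, 500.0
        t = np.arange(int(duration * fs)) / fs
        for _ in range(5):
            theta = sum(rng.uniform(0, 2) * np.sin(2 * np.pi * f * t
                                                   + rng.uniform(0, 6))
                        for f in (0.3, 0.7, 1.3))
            theta_dot = np.gradient(theta, 1 / fs)
            res = compute_score(PendulumTrace(t, theta, theta_dot), params)
            assert res.score <= params.k * params.angle_tol * duration + 1e-6

    def test_intervals_disjoint_and_ordered(self, params):
        trace = _hold_trace([(0.2, 0.0), (0.5, math.pi), (0.3, 0.0),
                             (0.4, math.pi), (0.2, 0.0)])
        iv = compute_score(trace, params).inversion_intervals
        flat = [x for pair in iv for x in pair]
        assert flat == sorted(flat)


@settings(derandomize=True, max_examples=100)
@given(theta=st.floats(-50, 50))
def test_wrap_angle_range_and_identity(theta):
    w = wrap_angle(theta)
    assert -math.pi < w <= math.pi
    assert math.cos(w) == pytest.approx(math.cos(theta), abs=1e-9)
    assert math.sin(w) == pytest.approx(math.sin(theta), abs=1e-9)


def test_trajectory_from_positions_consistency():
    t = np.arange(0, 5, 0.01)
    y = 0.1 * np.sin(2 * np.pi * 0.8 * t)
    pivot = PivotTrajectory.from_positions(t, y, np.zeros_like(t))
    assert np.allclose(pivot.y_dot[5:-5],
                       0.1 * 2 * np.pi * 0.8 * np.cos(2 * np.pi * 0.8 * t)[5:-5],
                       atol=1e-3)
    with pytest.raises(ValueError):
        PivotTrajectory.from_positions(t[::-1], y, np.zeros_like(t))
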