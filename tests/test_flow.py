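"""Phase alignment, flow costs, the regularized optimizer, and transport."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from contourflow.flow import (
    FlowStep,
    CostBreakdown,
    FlowViolationError,
    MarkerDensity,
    MarkerSet,
    PhaseTieWarning,
    align_track,
    compute_global_flow,
    compute_local_flow,
    cost_F,
    cost_S,
    cost_U,
    decompose_velocity,
    detect_mapping_violations,
    phase_align,
    solve_flow_step,
    transport_density,
    uniform_markers,
)
from contourflow.geometry import SmoothContour, fit_smooth_contour, reparametrize_arclength
from conftest import TWO_PI, make_circle, circle_polyline


def make_step(source_angles, lifted_target, frame=0):
    """Hand-construct a FlowStep without running the optimizer."""
    src = MarkerSet(frame, np.asarray(source_angles, dtype=float))
    lifted = np.asarray(lifted_target, dtype=float)
    tgt = MarkerSet(frame + 1, np.mod(lifted, TWO_PI))
    gaps = np.concatenate([np.diff(lifted), [lifted[0] + TWO_PI - lifted[-1]]])
    viol = [int(i) for i in np.flatnonzero(gaps <= 0)]
    return FlowStep(source=src, target=tgt, lam=0.0,
                    costs=CostBreakdown(0.0, 0.0, 0.0), violations=viol,
                    converged=True, iterations=0, lifted_target=lifted)


class TestPhaseAlign:
    def test_identical_contours_zero_shift(self, ellipse):
        pa, _ = phase_align(ellipse, ellipse)
        assert min(pa.shift, TWO_PI - pa.shift) < 1e-6

    def test_known_parametrization_shift_recovered(self, ellipse):
        # oracle: exhaustive grid search at 1e-4 resolution over the
        # discretized objective
        shifted = ellipse.shifted(-0.3)  # Psi(theta) = Phi(theta + 0.3)
        pa, aligned = phase_align(ellipse, shifted)
        grid = np.linspace(0, TWO_PI, 200, endpoint=False)
        ref = ellipse.evaluate(grid)
        taus = np.arange(0.29, 0.31, 1e-4)
        objs = [np.sum((shifted.evaluate(np.mod(grid - t, TWO_PI)) - ref) ** 2)
                for t in taus]
        tau_oracle = taus[int(np.argmin(objs))]
        assert abs(pa.shift - tau_oracle) < 1e-3
        assert np.max(np.abs(aligned.evaluate(grid) - ref)) < 1e-6

    def test_realigning_after_shift_gives_zero(self, ellipse):
        _, aligned = phase_align(ellipse, ellipse.shifted(-0.8))
        pa2, _ = phase_align(ellipse, aligned)
        assert min(pa2.shift, TWO_PI - pa2.shift) < 1e-6

    def test_flat_objective_warns_and_takes_smallest_shift(self, unit_circle):
        # a pure second-harmonic curve has zero cross-spectrum with the
        # harmonic-1 circle at every shift, so the objective is exactly flat
        theta = TWO_PI * np.arange(64) / 64
        pts = 0.5 * np.column_stack([np.cos(2 * theta), np.sin(2 * theta)])
        weird = SmoothContour(
            weights=np.linalg.solve(
                _gram(theta, 0.5), pts),
            support_angles=theta, kernel_scale=0.5, noise_level=1e-6)
        with pytest.warns(PhaseTieWarning):
            pa, _ = phase_align(unit_circle, weird)
        assert pa.tie
        assert pa.shift == 0.0


def _gram(angles, r):
    from contourflow.geometry import _poisson
    g = _poisson(angles[None, :] - angles[:, None], r)
    g[np.diag_indices_from(g)] += 1e-12
    return g


class TestCosts:
    def test_cost_F_zero_for_static_identity(self, unit_circle):
        m = uniform_markers(32)
        assert cost_F(m, m, unit_circle, unit_circle, 1.0) == 0.0

    def test_cost_F_translation_gives_squared_speed(self, unit_circle):
        moved = make_circle(1.0, 200, center=(1.0, 0.0))
        m = uniform_markers(64)
        assert abs(cost_F(m, m, unit_circle, moved, 1.0) - 1.0) < 1e-6

    def test_cost_F_matches_direct_summation(self, unit_circle, ellipse):
        rng = np.random.default_rng(3)
        src = MarkerSet(0, np.sort(rng.uniform(0, TWO_PI, 8)))
        tgt = MarkerSet(1, np.sort(rng.uniform(0, TWO_PI, 8)))
        dt = 0.7
        direct = sum(
            np.sum((ellipse.evaluate([b])[0] - unit_circle.evaluate([a])[0]) ** 2)
            for a, b in zip(src.angles, tgt.angles)) / (8 * dt * dt)
        assert abs(cost_F(src, tgt, unit_circle, ellipse, dt) - direct) < 1e-12 * direct

    @pytest.mark.parametrize("n", [4, 17, 400])
    def test_cost_U_minimal_for_uniform_spacing(self, n):
        assert abs(cost_U(uniform_markers(n)) - 4 * np.pi**2) < 1e-9

    def test_cost_U_handworked_nonuniform_example(self):
        m = MarkerSet(0, np.array([0.0, np.pi, 5 * np.pi / 4, 3 * np.pi / 2]))
        # gaps (pi, pi/4, pi/4, pi/2): U = 4*(pi^2 + pi^2/16 + pi^2/16 + pi^2/4)
        assert abs(cost_U(m) - 5.5 * np.pi**2) < 1e-12

    @given(st.lists(st.floats(0.01, TWO_PI - 0.01), min_size=3, max_size=20,
                    unique=True))
    @settings(max_examples=50, deadline=None)
    def test_cost_U_lower_bound(self, angles):
        m = MarkerSet(0, np.sort(np.array(angles)))
        assert cost_U(m) >= 4 * np.pi**2 - 1e-9

    @pytest.mark.parametrize("n", [3, 8])
    def test_cost_S_equal_spacing(self, n):
        assert abs(cost_S(uniform_markers(n)) - np.log(TWO_PI / n)) < 1e-12

    def test_cost_S_maximized_by_uniform_spacing(self):
        rng = np.random.default_rng(0)
        s_uniform = cost_S(uniform_markers(8))
        for _ in range(20):
            m = MarkerSet(0, np.sort(rng.uniform(0, TWO_PI, 8)))
            assert cost_S(m) <= s_uniform + 1e-12

    def test_cost_S_zero_gap_guard(self):
        m = make_step([0.0, 1.0, 2.0], [0.0, 1.0, 1.0]).target
        with pytest.raises(ValueError):
            cost_S(MarkerSet(0, np.array([0.0, 1.0, 1.0])))


class TestSolveFlowStep:
    def test_static_frames_identity_solution(self, unit_circle):
        src = uniform_markers(32)
        for lam in (0.0, 0.1, 1000.0):
            step = solve_flow_step(unit_circle, unit_circle, src, lam, 1.0)
            np.testing.assert_allclose(step.target.angles, src.angles, atol=1e-12)
            assert step.costs.F == 0.0
            assert abs(step.costs.U - 4 * np.pi**2) < 1e-9

    def test_matches_coordinate_descent_oracle_on_small_instance(self, unit_circle):
        # independent oracle: cyclic per-marker exhaustive refinement on a
        # fine angular grid for the translated-circle pair, N = 8
        moved = make_circle(1.0, 100, center=(0.3, 0.1), frame=1)
        src = uniform_markers(8)
        p = unit_circle.evaluate(src.angles)

        def total_cost(phi, lam):
            d = moved.evaluate(np.mod(phi, TWO_PI)) - p
            f = np.sum(d * d) / 8
            g = np.concatenate([np.diff(phi), [phi[0] + TWO_PI - phi[-1]]])
            return f + lam * 8 * np.sum(g * g)

        for lam in (0.0, 0.1, 1000.0):
            phi = src.angles.astype(float).copy()
            for _ in range(100):
                before = phi.copy()
                for i in range(8):
                    cand = phi[i] + np.linspace(-0.6, 0.6, 121)
                    vals = []
                    for x in cand:
                        q = phi.copy()
                        q[i] = x
                        vals.append(total_cost(q, lam))
                    phi[i] = cand[int(np.argmin(vals))]
                if np.max(np.abs(phi - before)) < 1e-12:
                    break
            oracle = total_cost(phi, lam)
            step = solve_flow_step(unit_circle, moved, src, lam, 1.0)
            ours = step.costs.F + lam * step.costs.U
            assert ours <= oracle + 1e-6 * (1 + abs(oracle))

    def test_concentric_circles_strong_regularization_radial_map(self):
        inner = make_circle(1.0, 100, frame=0)
        outer = make_circle(1.1, 100, frame=1)
        step = solve_flow_step(inner, outer, uniform_markers(50), 1000.0, 1.0)
        gaps = step.target_gaps()
        np.testing.assert_allclose(gaps, TWO_PI / 50, rtol=1e-6)
        assert abs(step.costs.F - 0.01) < 1e-4


class TestMappingViolations:
    def test_strictly_increasing_is_clean(self):
        assert detect_mapping_violations(np.array([0.1, 0.5, 1.7, 3.0, 5.5])) == []

    def test_swapped_neighbors_single_index(self):
        assert detect_mapping_violations(np.array([0.1, 0.5, 0.4, 3.0])) == [1]

    def test_wrap_seam_violation_reported_at_last_index(self):
        # lifted sequence spanning more than 2 pi: theta_0 + 2pi <= theta_{N-1}
        lifted = np.array([0.1, 2.0, 4.0, 0.1 + TWO_PI + 0.05])
        assert detect_mapping_violations(lifted) == [3]

    def test_markerset_with_single_wrap_is_clean(self):
        m = MarkerSet(0, np.array([5.0, 6.0, 0.5, 2.0]))
        assert detect_mapping_violations(m) == []


class TestTrackFlows:
    def test_static_track_constant_trajectories(self, unit_circle):
        track = [unit_circle, unit_circle, unit_circle]
        markers = compute_global_flow(track, 1000.0, 24, 1.0)
        for m in markers:
            np.testing.assert_allclose(m.angles, markers[0].angles, atol=1e-10)

    def test_expanding_circle_markers_stay_put_in_angle(self):
        track = [make_circle(1.0 + 0.1 * k, 100, frame=k) for k in range(4)]
        markers = compute_global_flow(track, 1000.0, 32, 1.0)
        for m in markers[1:]:
            np.testing.assert_allclose(
                np.mod(m.angles - markers[0].angles + np.pi, TWO_PI) - np.pi,
                0.0, atol=1e-3)

    def test_bump_track_has_no_violations_and_uniform_spacing(self, bump_track):
        _, contours, _ = bump_track
        markers = compute_global_flow(contours, 1000.0, 100, 1.0)
        for m in markers:
            gaps = m.cyclic_gaps()
            assert np.all(gaps > 0)
            assert np.max(np.abs(gaps - TWO_PI / 100)) < 0.01 * TWO_PI / 100

    def test_local_flow_reinitialization_independence(self, bump_track):
        _, contours, _ = bump_track
        full = compute_local_flow(contours[:6], 0.1, 50, 1.0)
        tail = compute_local_flow(contours[1:6], 0.1, 50, 1.0)
        for a, b in zip(full[1:], tail):
            np.testing.assert_array_equal(a.lifted_target, b.lifted_target)

    def test_static_local_flow_is_identity(self, unit_circle):
        steps = compute_local_flow([unit_circle] * 3, 0.1, 40, 1.0)
        for s in steps:
            np.testing.assert_allclose(s.target.angles, s.source.angles, atol=1e-12)

    def test_weak_limit_approaches_nearest_point_map(self):
        # monotone convex pair: unit circle into a slightly shifted larger circle
        prev = make_circle(1.0, 150, frame=0)
        nxt = make_circle(1.25, 150, center=(0.1, 0.0), frame=1)
        src = uniform_markers(24)
        step = solve_flow_step(prev, nxt, src, 1e-9, 1.0)
        dense = np.linspace(0, TWO_PI, 20000, endpoint=False)
        cloud = nxt.evaluate(dense)
        targets = nxt.evaluate(step.target.angles)
        for i, a in enumerate(src.angles):
            p = prev.evaluate([a])[0]
            nearest = cloud[np.argmin(np.sum((cloud - p) ** 2, axis=1))]
            assert np.hypot(*(targets[i] - nearest)) < 2e-3

    def test_gap_cv_decreases_with_regularization(self, bump_pair):
        prev, nxt = bump_pair
        src = uniform_markers(100)
        cvs = []
        for lam in (0.1, 10.0, 1000.0):
            step = solve_flow_step(prev, nxt, src, lam, 1.0)
            gaps = step.target_gaps()
            cvs.append(np.std(gaps) / np.mean(gaps))
        assert cvs[0] > cvs[1] > cvs[2]


class TestTransportAndVelocity:
    def test_uniform_density_under_uniform_stretch(self):
        step = make_step(TWO_PI * np.arange(4) / 4, TWO_PI * np.arange(4) / 4 + 0.3)
        out = transport_density(MarkerDensity(np.full(4, 0.25)), step)
        np.testing.assert_allclose(out.weights, 0.25)

    def test_mass_conserved(self):
        rng = np.random.default_rng(8)
        src = np.sort(rng.uniform(0, TWO_PI, 12))
        src[0] = 0.0
        tgt = np.sort(rng.uniform(0, TWO_PI, 12))
        step = make_step(src, tgt)
        w = rng.uniform(0.1, 1.0, 12)
        out = transport_density(MarkerDensity(w / w.sum()), step)
        assert abs(out.weights.sum() - 1.0) < 1e-12

    def test_handworked_doubling_and_halving(self):
        # half the circle's gaps double, the other half shrink accordingly:
        # weights scale by 1/stretch before renormalization
        src = TWO_PI * np.arange(4) / 4
        tgt = np.array([0.0, np.pi * 0.75, np.pi, np.pi * 1.75])
        step = make_step(src, tgt)
        out = transport_density(MarkerDensity(np.full(4, 0.25)), step)
        stretch = np.array([1.5, 0.5, 1.5, 0.5])
        expect = (0.25 / stretch) / np.sum(0.25 / stretch)
        np.testing.assert_allclose(out.weights, expect)

    def test_violating_step_rejected(self):
        step = make_step([0.0, 1.0, 2.0, 3.0], [0.0, 2.0, 1.5, 3.0])
        with pytest.raises(FlowViolationError):
            transport_density(MarkerDensity(np.full(4, 0.25)), step)

    def test_expanding_circle_velocity_is_purely_normal(self):
        inner = make_circle(1.0, 100, frame=0)
        outer = make_circle(1.1, 100, frame=1)
        step = solve_flow_step(inner, outer, uniform_markers(40), 1000.0, 1.0)
        v = decompose_velocity(step, inner, outer, 1.0)
        np.testing.assert_allclose(v.normal_speed, 0.1, atol=1e-3)
        np.testing.assert_allclose(v.tangential_speed, 0.0, atol=1e-3)

    def test_pure_reparametrization_has_no_normal_speed(self, unit_circle):
        # the chord of a tangential shift delta has a normal component of
        # order delta^2, vanishing in the continuum limit
        src = uniform_markers(16)
        delta = 0.01
        step = make_step(src.angles, src.angles + delta)
        v = decompose_velocity(step, unit_circle, unit_circle, 1.0)
        np.testing.assert_allclose(v.normal_speed, 0.0, atol=2 * delta**2)
        assert np.all(np.abs(v.tangential_speed - delta) < 2 * delta**2)

    def test_pythagorean_identity(self, unit_circle, ellipse):
        rng = np.random.default_rng(2)
        src = MarkerSet(0, np.sort(rng.uniform(0, TWO_PI, 10)))
        tgt_l = np.sort(rng.uniform(0, TWO_PI, 10))
        step = make_step(src.angles, tgt_l)
        v = decompose_velocity(step, unit_circle, ellipse, 0.5)
        d = (ellipse.evaluate(step.target.angles)
             - unit_circle.evaluate(src.angles)) / 0.5
        np.testing.assert_allclose(v.normal_speed**2 + v.tangential_speed**2,
                                   np.sum(d * d, axis=1), rtol=1e-10)
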