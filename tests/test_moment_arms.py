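"""Geometric moment arms: common perpendicular, scalar conversion, series."""

import numpy as np
import pytest

from geomma.moment_arms import (AxisLine, JointDefinition, MuscleLine,
                                common_perpendicular, mma_time_series,
                                mma_triple, normalise_mma, rmse,
                                scalar_moment_arm)
from geomma.rigid_kinematics import AnatomicalFrame
from geomma.synthetic_rig import MotionProgram, simulate_trial
from conftest import random_transform


def torque_oracle(axis: AxisLine, muscle: MuscleLine) -> float:
    """Torque per unit force about the axis: ((p - a) x F_hat) . a_hat,
    valid for any point p on the muscle line."""
    return float(np.cross(muscle.p_prox - axis.point, muscle.direction)
                 @ axis.direction)


def grid_min_distance(a: AxisLine, b: AxisLine, half_range: float = 60.0,
                      n: int = 2000) -> float:
    """Exhaustive minimum distance between two lines over an n x n grid of
    the two line parameters, refined once around the coarse minimum."""
    u, v, w = a.direction, b.direction, b.point - a.point

    def d2_grid(s, t):
        # ||w + t v - s u||^2 expanded in the two parameters
        return (w @ w
                + (s ** 2)[:, None] + (t ** 2)[None, :]
                - 2 * (w @ u) * s[:, None] + 2 * (w @ v) * t[None, :]
                - 2 * (u @ v) * s[:, None] * t[None, :])

    s = np.linspace(-half_range, half_range, n)
    t = np.linspace(-half_range, half_range, n)
    coarse = d2_grid(s, t)
    i, j = np.unravel_index(np.argmin(coarse), coarse.shape)
    step = s[1] - s[0]
    s2 = np.linspace(s[i] - 2 * step, s[i] + 2 * step, n)
    t2 = np.linspace(t[j] - 2 * step, t[j] + 2 * step, n)
    return float(np.sqrt(max(d2_grid(s2, t2).min(), 0.0)))


class TestCommonPerpendicular:
    def test_orthogonal_skew_pair(self):
        a = AxisLine.through([0, 0, 0], [1, 0, 0])
        b = AxisLine.through([0, 0, 5], [0, 1, 0])
        perp = common_perpendicular(a, b)
        np.testing.assert_allclose(perp.r_vec, [0, 0, 5], atol=1e-12)
        assert perp.length == pytest.approx(5.0)
        assert not perp.degenerate

    def test_intersecting_lines_zero_segment(self):
        a = AxisLine.through([0, 0, 0], [1, 0, 0])
        b = AxisLine.through([3, 0, 0], [1, 1, 0])
        perp = common_perpendicular(a, b)
        assert perp.length == pytest.approx(0.0, abs=1e-12)

    def test_parallel_lines_flagged(self):
        a = AxisLine.through([0, 0, 0], [1, 0, 0])
        b = AxisLine.through([5, 3, 0], [1, 0, 0])
        perp = common_perpendicular(a, b)
        assert perp.degenerate
        assert perp.length == pytest.approx(3.0)

    def test_perpendicular_to_both_lines(self, rng):
        for _ in range(100):
            a = AxisLine.through(rng.normal(scale=10, size=3),
                                 rng.normal(size=3))
            b = AxisLine.through(rng.normal(scale=10, size=3),
                                 rng.normal(size=3))
            perp = common_perpendicular(a, b)
            if perp.degenerate or perp.length < 1e-9:
                continue
            assert abs(perp.r_vec @ a.direction) < 1e-9 * perp.length
            assert abs(perp.r_vec @ b.direction) < 1e-9 * perp.length
            assert perp.length == pytest.approx(
                float(np.linalg.norm(perp.foot_muscle - perp.foot_axis)))

    def test_against_grid_search_oracle(self, rng):
        """Shortest-segment length equals an exhaustive 2000x2000 parameter
        grid search to 1e-3 mm on random skew pairs."""
        for _ in range(200):
            a = AxisLine.through(rng.uniform(-10, 10, 3), rng.normal(size=3))
            b = AxisLine.through(rng.uniform(-10, 10, 3), rng.normal(size=3))
            if abs(a.direction @ b.direction) > 0.95:
                continue  # near-parallel: optimum can leave the grid range
            perp = common_perpendicular(a, b)
            if perp.degenerate:
                continue
            assert perp.length == pytest.approx(grid_min_distance(a, b),
                                                abs=1e-3)


class TestScalarMomentArm:
    def test_planar_lever(self):
        axis = AxisLine.through([0, 0, 0], [0, 0, 1])
        muscle = MuscleLine([3, 0, 0], [3, 5, 0])
        assert scalar_moment_arm(axis, muscle) == pytest.approx(3.0, abs=1e-12)

    def test_force_parallel_to_axis_is_zero(self):
        axis = AxisLine.through([0, 0, 0], [0, 0, 1])
        muscle = MuscleLine([3, 0, 0], [3, 0, 4])
        assert scalar_moment_arm(axis, muscle) == pytest.approx(0.0, abs=1e-12)

    def test_matches_torque_per_unit_force_oracle(self, rng):
        for _ in range(500):
            axis = AxisLine.through(rng.normal(scale=10, size=3),
                                    rng.normal(size=3))
            muscle = MuscleLine(rng.normal(scale=10, size=3),
                                rng.normal(scale=10, size=3))
            assert scalar_moment_arm(axis, muscle) == pytest.approx(
                torque_oracle(axis, muscle), abs=1e-9)

    def test_independent_of_point_and_marker_spacing(self, rng):
        axis = AxisLine.through(rng.normal(size=3), rng.normal(size=3))
        p, q = rng.normal(scale=10, size=3), rng.normal(scale=10, size=3)
        base = scalar_moment_arm(axis, MuscleLine(p, q))
        f_hat = MuscleLine(p, q).direction
        for shift in rng.uniform(-20, 20, size=8):
            for scale in (0.1, 1.0, 7.3):
                moved = MuscleLine(p + shift * f_hat,
                                   p + shift * f_hat + scale * (q - p))
                assert scalar_moment_arm(axis, moved) == pytest.approx(
                    base, abs=1e-9)

    def test_magnitude_bounded_by_perpendicular_length(self, rng):
        for _ in range(200):
            axis = AxisLine.through(rng.normal(size=3), rng.normal(size=3))
            muscle = MuscleLine(rng.normal(scale=10, size=3),
                                rng.normal(scale=10, size=3))
            perp = common_perpendicular(axis, muscle.as_line())
            assert abs(scalar_moment_arm(axis, muscle)) <= perp.length + 1e-12

    def test_equality_iff_force_perpendicular_to_axis(self):
        axis = AxisLine.through([0, 0, 0], [0, 0, 1])
        in_plane = MuscleLine([4, 0, 1], [4, 6, 1])
        perp = common_perpendicular(axis, in_plane.as_line())
        assert abs(scalar_moment_arm(axis, in_plane)) == pytest.approx(
            perp.length, abs=1e-12)
        tilted = MuscleLine([4, 0, 1], [4, 6, 4])
        perp_t = common_perpendicular(axis, tilted.as_line())
        assert abs(scalar_moment_arm(axis, tilted)) < perp_t.length - 1e-6

    def test_rigid_motion_equivariance(self, rng):
        """One rigid transform applied to frame and muscle leaves all three
        scalar moment arms unchanged."""
        frame = AnatomicalFrame.from_transform(random_transform(rng))
        muscle = MuscleLine(rng.normal(scale=10, size=3),
                            rng.normal(scale=10, size=3))
        base = mma_triple(frame, muscle).as_array()
        t = random_transform(rng)
        moved_frame = frame.transformed(t)
        moved_muscle = MuscleLine(t.apply(muscle.p_prox), t.apply(muscle.p_dist))
        np.testing.assert_allclose(mma_triple(moved_frame, moved_muscle).as_array(),
                                   base, atol=1e-9)

    def test_flipping_markers_flips_sign(self, rng):
        axis = AxisLine.through(rng.normal(size=3), rng.normal(size=3))
        muscle = MuscleLine(rng.normal(scale=10, size=3),
                            rng.normal(scale=10, size=3))
        assert scalar_moment_arm(axis, muscle.flipped()) == pytest.approx(
            -scalar_moment_arm(axis, muscle), abs=1e-12)

    def test_rejects_zero_length_muscle(self):
        with pytest.raises(ValueError, match="coincident"):
            MuscleLine([1, 2, 3], [1, 2, 3])


class TestMMATriple:
    def test_muscle_along_axis_through_origin_all_zero(self):
        frame = AnatomicalFrame([0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1])
        muscle = MuscleLine([-5, 0, 0], [5, 0, 0])
        np.testing.assert_allclose(mma_triple(frame, muscle).as_array(), 0.0,
                                   atol=1e-12)

    def test_planar_lever_pattern_under_axis_permutation(self):
        frame = AnatomicalFrame([0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1])
        # lever arm 3 along x, force along y -> moment about z only
        np.testing.assert_allclose(
            mma_triple(frame, MuscleLine([3, 0, 0], [3, 5, 0])).as_array(),
            [0, 0, 3], atol=1e-12)
        # cyclic permutation: lever along y, force along z -> moment about x
        np.testing.assert_allclose(
            mma_triple(frame, MuscleLine([0, 3, 0], [0, 3, 5])).as_array(),
            [3, 0, 0], atol=1e-12)

    def test_components_match_independent_calls(self, rng):
        frame = AnatomicalFrame.from_transform(random_transform(rng))
        muscle = MuscleLine(rng.normal(scale=10, size=3),
                            rng.normal(scale=10, size=3))
        triple = mma_triple(frame, muscle).as_array()
        for k, axis_vec in enumerate((frame.x_axis, frame.y_axis, frame.z_axis)):
            single = scalar_moment_arm(AxisLine(frame.origin, axis_vec), muscle)
            assert triple[k] == pytest.approx(single, abs=1e-12)


class TestMMATimeSeries:
    def test_static_trial_gives_constant_series(self, hinge_rig):
        program = MotionProgram({"rz": np.full(30, 17.0)})
        sim = simulate_trial(hinge_rig, program)
        joint = JointDefinition(name="j", proximal_bone="proximal",
                                distal_bone="distal")
        series = mma_time_series(sim.trial, joint, ("flexor_prox", "flexor_dist"))
        np.testing.assert_allclose(series.to_numpy() - series.to_numpy()[0],
                                   0.0, atol=1e-12)

    def test_noise_free_hinge_matches_closed_form(self, hinge_rig):
        program = MotionProgram.sweep("rz", -40.0, 40.0, 60)
        sim = simulate_trial(hinge_rig, program)
        joint = JointDefinition(name="j", proximal_bone="proximal",
                                distal_bone="distal")
        series = mma_time_series(sim.trial, joint, ("flexor_prox", "flexor_dist"))
        np.testing.assert_allclose(series.to_numpy(),
                                   sim.true_mma["flexor"].to_numpy(), atol=1e-6)

    def test_missing_marker_frames_reported_by_index(self, hinge_rig):
        program = MotionProgram.sweep("rz", 0.0, 10.0, 10)
        sim = simulate_trial(hinge_rig, program)
        sim.trial.markers["flexor_dist"][np.array([2, 7])] = np.nan
        joint = JointDefinition(name="j", proximal_bone="proximal",
                                distal_bone="distal")
        with pytest.raises(ValueError, match=r"frames \[2, 7\]"):
            mma_time_series(sim.trial, joint, ("flexor_prox", "flexor_dist"))

    def test_unknown_marker_rejected(self, hinge_rig):
        sim = simulate_trial(hinge_rig, MotionProgram.sweep("rz", 0, 1, 5))
        joint = JointDefinition(name="j", proximal_bone="proximal",
                                distal_bone="distal")
        with pytest.raises(KeyError, match="nope"):
            mma_time_series(sim.trial, joint, ("nope", "flexor_dist"))


class TestRmseAndNormalise:
    def test_rmse_identical_and_offset(self, rng):
        x = rng.normal(size=100)
        assert rmse(x, x) == 0.0
        assert rmse(x, x + 2.5) == pytest.approx(2.5)

    def test_rmse_matches_direct_formula(self, rng):
        a, b = rng.normal(size=64), rng.normal(size=64)
        assert rmse(a, b) == pytest.approx(
            float(np.sqrt(np.mean((a - b) ** 2))), abs=1e-12)

    def test_rmse_rejects_length_mismatch(self):
        with pytest.raises(ValueError, match="lengths differ"):
            rmse(np.zeros(3), np.zeros(4))

    def test_normalise_joint_peak_maps_to_unit(self):
        a, b = normalise_mma([1.0, -4.0], [2.0, 0.5])
        assert np.abs(np.concatenate([a, b])).max() == pytest.approx(1.0)
        assert a[1] == pytest.approx(-1.0)

    def test_normalise_preserves_sign_and_scale_invariance(self, rng):
        x, y = rng.normal(size=50), rng.normal(size=50)
        a1, b1 = normalise_mma(x, y)
        a2, b2 = normalise_mma(3.7 * x, 3.7 * y)
        np.testing.assert_allclose(a1, a2, atol=1e-12)
        np.testing.assert_allclose(b1, b2, atol=1e-12)
        assert np.all(np.sign(a1) == np.sign(x))

    def test_normalise_rejects_all_zero(self):
        with pytest.raises(ValueError, match="all-zero"):
            normalise_mma(np.zeros(5), np.zeros(5))
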