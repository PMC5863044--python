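"""Unit tests for rotation-centre estimation, angular-velocity statistics,
checkpoint aggregation and group comparisons."""

import numpy as np
import pytest

import predflow as pf
from predflow.flow import FlowParams, FlowVectorSet, compute_flow
from predflow.motion import (
    AngularVelocitySummary,
    NoMotionError,
    NoUsableVectorsError,
    RotationCenter,
    angular_velocity_stats,
    checkpoint_summary,
    compare_groups,
    estimate_center,
)
from predflow.stimuli import rigid_rotation_flow_oracle, warp_rigid_rotation


def _oracle_flow(center, omega, points, pair=""):
    vectors = rigid_rotation_flow_oracle(center, omega, points)
    return FlowVectorSet(points, vectors, np.ones(len(points), bool), pair)


class TestEstimateCenter:
    def test_propeller_center_within_two_px(self):
        spec = pf.PropellerSpec(rpm=15.0)
        video = pf.make_propeller_video(spec)
        c = estimate_center(video)
        cx, cy = spec.center_xy
        assert np.hypot(c.x - cx, c.y - cy) < 2.0
        assert c.source == "estimated-from-motion"

    def test_offcenter_propeller(self):
        spec = pf.PropellerSpec(rpm=15.0, center=(100.0, 50.0))
        c = estimate_center(pf.make_propeller_video(spec))
        assert np.hypot(c.x - 100, c.y - 50) < 2.0

    def test_static_video_signals_no_motion(self):
        video = pf.make_propeller_video(pf.PropellerSpec(rpm=0.0))
        with pytest.raises(NoMotionError):
            estimate_center(video)

    def test_needs_two_frames(self):
        video = pf.FrameSequence(np.zeros((1, 8, 8, 3), np.float32))
        with pytest.raises(ValueError):
            estimate_center(video)


class TestAngularVelocityStats:
    @pytest.mark.parametrize("omega", [-0.1, -0.05, 0.05, 0.1])
    def test_oracle_field_recovered_within_one_percent(self, omega, grid_points):
        """Exact rotation fields give the generating omega within 1% with
        near-zero standard error, and the correct sign."""
        center = RotationCenter(80.0, 60.0)
        flow = _oracle_flow((80.0, 60.0), omega, grid_points)
        s = angular_velocity_stats(flow, center)
        assert abs(s.mean - omega) / abs(omega) < 0.01
        assert np.sign(s.mean) == np.sign(omega)
        assert s.se < 1e-6

    def test_zero_displacements_zero_stats(self, grid_points):
        flow = FlowVectorSet(grid_points, np.zeros_like(grid_points),
                             np.ones(len(grid_points), bool))
        s = angular_velocity_stats(flow, RotationCenter(80, 60))
        assert s.mean == 0.0
        assert s.se == 0.0

    def test_downward_vector_at_three_oclock_is_clockwise_positive(self):
        """Sign convention: at the 3-o'clock position a downward (+y)
        displacement is clockwise, hence positive."""
        flow = FlowVectorSet(np.array([[100.0, 60.0]]), np.array([[0.0, 1.0]]),
                             np.array([True]))
        s = angular_velocity_stats(flow, RotationCenter(80, 60))
        assert s.mean > 0

    def test_exclusion_radius(self):
        pts = np.array([[81.0, 60.0], [80.0, 61.0]])  # within 5 px of centre
        flow = FlowVectorSet(pts, np.ones_like(pts), np.array([True, True]))
        with pytest.raises(NoUsableVectorsError):
            angular_velocity_stats(flow, RotationCenter(80, 60), min_radius=5.0)

    def test_all_untracked_rejected(self):
        flow = FlowVectorSet(np.array([[10.0, 10.0]]), np.zeros((1, 2)),
                             np.array([False]))
        with pytest.raises(NoUsableVectorsError):
            angular_velocity_stats(flow, RotationCenter(80, 60))

    def test_coord_scale_leaves_omega_invariant(self, grid_points):
        """Rescaling into the original stimulus frame scales r and v alike,
        so omega is unchanged when the centre is scaled too."""
        flow = _oracle_flow((80.0, 60.0), 0.05, grid_points)
        s1 = angular_velocity_stats(flow, RotationCenter(80, 60), coord_scale=1.0)
        s8 = angular_velocity_stats(flow, RotationCenter(640, 480), coord_scale=8.0,
                                    min_radius=40.0)
        assert s8.mean == pytest.approx(s1.mean, rel=1e-6)

    def test_mirror_antisymmetry(self, texture, grid_points):
        """Horizontally flipping both frames of a pair negates the mean
        angular velocity."""
        center = (80.0, 60.0)
        warped = warp_rigid_rotation(texture, center, 0.05)
        params = FlowParams(window_size=21)
        f = compute_flow(texture, warped, grid_points, params)
        s = angular_velocity_stats(f, RotationCenter(*center), min_radius=15.0)

        w = texture.shape[1]
        tex_m, warped_m = texture[:, ::-1], warped[:, ::-1]
        pts_m = grid_points.copy()
        pts_m[:, 0] = (w - 1) - pts_m[:, 0]
        f_m = compute_flow(tex_m, warped_m, pts_m, params)
        center_m = RotationCenter((w - 1) - center[0], center[1])
        s_m = angular_velocity_stats(f_m, center_m, min_radius=15.0)
        assert s_m.mean == pytest.approx(-s.mean, rel=0.05)


class TestCheckpointSummary:
    def _summaries(self, means, frames):
        return [AngularVelocitySummary(np.array([m]), frames_seen=f)
                for m, f in zip(means, frames)]

    def test_window_selects_n_checkpoints(self):
        frames = [100, 200, 300, 400, 500, 600, 700, 800, 900, 1000]
        s = self._summaries(np.linspace(0, 1, 10), frames)
        agg = checkpoint_summary(s, window=(400, 1000))
        assert agg.n == 7

    def test_identical_means_zero_se(self):
        s = self._summaries([0.3, 0.3, 0.3], [1, 2, 3])
        agg = checkpoint_summary(s, window=(0, 10))
        assert agg.se == 0.0

    def test_hand_computed_mean_and_se(self):
        s = self._summaries([1.0, 2.0, 3.0], [1, 2, 3])
        agg = checkpoint_summary(s, window=(0, 10))
        assert agg.mean == pytest.approx(2.0)
        assert agg.se == pytest.approx(1.0 / np.sqrt(3), rel=1e-9)

    def test_empty_window_rejected(self):
        s = self._summaries([1.0], [100])
        with pytest.raises(ValueError, match="window"):
            checkpoint_summary(s, window=(200, 300))


class TestCompareGroups:
    def test_student_df_for_seven_vs_seven(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(0, 1, 7), rng.normal(1, 1, 7)
        gc = compare_groups(a, b, test="student", alternative="less")
        assert gc.df == 12

    def test_identical_groups_t_zero_p_half(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        gc = compare_groups(a, a.copy(), test="student")
        assert gc.t == pytest.approx(0.0, abs=1e-12)
        assert gc.p == pytest.approx(0.5)

    def test_pooled_t_matches_hand_formula(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        b = np.array([2.0, 3.0, 4.0, 5.0])
        gc = compare_groups(a, b, test="student", alternative="less")
        sp2 = (a.var(ddof=1) * 3 + b.var(ddof=1) * 3) / 6
        t_hand = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / 4 + 1 / 4))
        assert gc.t == pytest.approx(t_hand, rel=1e-12)
        assert gc.df == 6

    def test_welch_df_never_exceeds_student_df(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            a = rng.normal(0, 1, rng.integers(3, 9))
            b = rng.normal(0, rng.uniform(0.5, 3), rng.integers(3, 9))
            w = compare_groups(a, b, test="welch")
            assert w.df <= len(a) + len(b) - 2 + 1e-9

    def test_absolute_compares_magnitudes(self):
        a = np.array([-3.0, -3.1, -2.9, -3.05])
        b = np.array([0.1, -0.1, 0.05, -0.05])
        gc = compare_groups(a, b, absolute=True, alternative="greater")
        assert gc.t > 0
        assert gc.p < 0.01

    def test_auto_picks_welch_for_unequal_sizes(self):
        rng = np.random.default_rng(2)
        gc = compare_groups(rng.normal(0, 1, 5), rng.normal(0, 1, 9))
        assert gc.test == "welch"

    def test_degenerate_groups_rejected(self):
        with pytest.raises(ValueError):
            compare_groups([1.0], [1.0, 2.0])
        with pytest.raises(ValueError, match="zero variance"):
            compare_groups([1.0, 1.0], [1.0, 1.0])


class TestRotationRateAnchor:
    def test_fifteen_rpm_is_0523_rad_per_frame(self):
        """15 rpm at 30 fps = 0.0523 rad/frame, the printed conversion."""
        omega = 15.0 * 2 * np.pi / (60.0 * 30.0)
        assert omega == pytest.approx(0.0523, abs=1e-4)

    def test_oracle_pipeline_recovers_propeller_rate(self, texture, grid_points):
        """A rigid 15-rpm warp pushed through flow + angular-velocity
        stages recovers 0.0523 rad/frame within 10%."""
        omega = 15.0 * 2 * np.pi / (60.0 * 30.0)
        center = (80.0, 60.0)
        warped = warp_rigid_rotation(texture, center, omega)
        f = compute_flow(texture, warped, grid_points, FlowParams(window_size=21))
        s = angular_velocity_stats(f, RotationCenter(*center), min_radius=15.0)
        assert abs(s.mean - omega) / omega < 0.10
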