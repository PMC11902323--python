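import math

import numpy as np
import pytest

from malletscore.errors import (CalibrationError, ConfigurationError,
                                DegenerateGeometryError, EmptyInputError)
from malletscore.geometry import (ArmSide, Criterion, angle_series,
                                  arm_length_ratio, elbow_angle,
                                  lower_arm_transverse_angle,
                                  mouth_touch_detected, upper_arm_angle)
from malletscore.keypoints_io import (MID_HIP, NECK, NOSE, Movement,
                                      PoseFrame, PoseSequence, View)
from malletscore.preprocessing import preprocess
from malletscore.synthetic import (NoiseModel, build_script,
                                   constant_pose_trial, render_script)

L = ArmSide.LEFT
R = ArmSide.RIGHT


def frame_with(points: dict[int, tuple[float, float]]) -> PoseFrame:
    kp = np.zeros((25, 3))
    kp[:, :2] = 10.0  # park unused keypoints away from the origin
    kp[:, 2] = 1.0
    for idx, (x, y) in points.items():
        kp[idx, :2] = (x, y)
    return PoseFrame(kp)


def law_of_cosines_angle(a, b, c):
    """Interior angle at vertex b of triangle (a, b, c), degrees."""
    ab = math.dist(a, b)
    cb = math.dist(c, b)
    ac = math.dist(a, c)
    return math.degrees(math.acos((ab ** 2 + cb ** 2 - ac ** 2)
                                  / (2 * ab * cb)))


class TestUpperArmAngle:
    def test_parallel_and_perpendicular(self):
        f = frame_with({NECK: (0, 0), MID_HIP: (0, 200),
                        L.shoulder: (50, 0), L.elbow: (50, 100)})
        assert upper_arm_angle(f, L) == pytest.approx(0.0, abs=1e-12)
        f = frame_with({NECK: (0, 0), MID_HIP: (0, 200),
                        L.shoulder: (50, 0), L.elbow: (150, 0)})
        assert upper_arm_angle(f, L) == pytest.approx(90.0, abs=1e-12)

    def test_generator_ground_truth_noise_free(self, model):
        seq = constant_pose_trial(Movement.GLOBAL_ABDUCTION, 137.5, model,
                                  n_frames=3)
        for side in (L, R):
            assert upper_arm_angle(seq.frames[0], side) == pytest.approx(
                137.5, abs=1e-6)

    def test_degenerate_geometry_raises(self):
        f = frame_with({NECK: (0, 0), MID_HIP: (0, 200),
                        L.shoulder: (50, 50), L.elbow: (50, 50)})
        with pytest.raises(DegenerateGeometryError):
            upper_arm_angle(f, L)


class TestElbowAngle:
    def test_collinear_and_right_angle(self):
        f = frame_with({L.shoulder: (0, 0), L.elbow: (0, 100),
                        L.wrist: (0, 200)})
        assert elbow_angle(f, L) == pytest.approx(180.0, abs=1e-12)
        f = frame_with({L.shoulder: (0, 0), L.elbow: (0, 100),
                        L.wrist: (100, 100)})
        assert elbow_angle(f, L) == pytest.approx(90.0, abs=1e-12)

    def test_matches_law_of_cosines_on_random_triples(self, rng):
        for _ in range(200):
            s, e, w = rng.uniform(-100, 100, (3, 2))
            if min(np.linalg.norm(s - e), np.linalg.norm(w - e)) < 1e-3:
                continue
            f = frame_with({L.shoulder: tuple(s), L.elbow: tuple(e),
                            L.wrist: tuple(w)})
            assert elbow_angle(f, L) == pytest.approx(
                law_of_cosines_angle(s, e, w), abs=1e-9)


class TestArmLengthRatio:
    def test_generator_ground_truth(self, model, calibration):
        # arm held in the image plane: pixel ratio equals the 3D ratio
        for side in (L, R):
            r = arm_length_ratio(calibration, side)
            assert r.ratio == pytest.approx(model.lower_arm / model.upper_arm,
                                            abs=1e-6)
            assert r.n_frames_used == calibration.n_frames

    def test_single_frame_equal_segments(self):
        f = frame_with({L.shoulder: (0, 0), L.elbow: (0, 120),
                        L.wrist: (120, 120)})
        seq = PoseSequence([f], Movement.GLOBAL_ABDUCTION, View.FRONTAL, "t")
        assert arm_length_ratio(seq, L).ratio == pytest.approx(1.0)

    def test_constant_pose_mean_equals_single_frame(self):
        f = frame_with({L.shoulder: (0, 0), L.elbow: (0, 100),
                        L.wrist: (80, 100)})
        frames = [PoseFrame(f.keypoints.copy(), i) for i in range(6)]
        seq = PoseSequence(frames, Movement.GLOBAL_ABDUCTION, View.FRONTAL, "t")
        assert arm_length_ratio(seq, L).ratio == pytest.approx(0.8)

    def test_no_valid_frames_raises(self):
        f = frame_with({L.shoulder: (0, 0), L.elbow: (0, 100),
                        L.wrist: (80, 100)})
        f.keypoints[L.wrist, 2] = 0.0
        seq = PoseSequence([f], Movement.GLOBAL_ABDUCTION, View.FRONTAL, "t")
        with pytest.raises(CalibrationError):
            arm_length_ratio(seq, L)


class TestLowerArmTransverseAngle:
    @pytest.fixture()
    def ratio(self, calibration):
        return arm_length_ratio(calibration, L)

    def test_in_plane_forearm_is_90(self, ratio):
        # projected length equals true length -> arccos(1)=0 -> 90 - 0
        f = frame_with({L.shoulder: (0, 0), L.elbow: (0, 100),
                        L.wrist: (100 * ratio.ratio, 100)})
        assert lower_arm_transverse_angle(f, L, ratio) == pytest.approx(
            90.0, abs=1e-9)

    def test_forearm_at_camera_is_0(self, ratio):
        f = frame_with({L.shoulder: (0, 0), L.elbow: (0, 100),
                        L.wrist: (0, 100)})
        assert lower_arm_transverse_angle(f, L, ratio) == pytest.approx(0.0)

    def test_noise_free_round_trip_recovers_commanded_angle(
            self, model, calibration):
        """3D pose -> frontal projection -> estimator is the identity."""
        for side in (L, R):
            ratio = arm_length_ratio(calibration, side)
            for phi in np.arange(-80.0, 80.5, 10.0):
                seq = constant_pose_trial(Movement.GLOBAL_EXTERNAL_ROTATION,
                                          float(phi), model, n_frames=3)
                got = lower_arm_transverse_angle(seq.frames[0], side, ratio)
                assert got == pytest.approx(phi, abs=1e-6)

    def test_ratio_clamped_above_one(self, ratio):
        # wrist "longer" than the calibrated forearm: clamp -> +/-90
        f = frame_with({L.shoulder: (0, 0), L.elbow: (0, 100),
                        L.wrist: (500, 100)})
        assert lower_arm_transverse_angle(f, L, ratio) == pytest.approx(90.0)

    def test_noise_amplification_grows_toward_90(self, model, calibration):
        """Fixed pixel jitter hurts most where the projected length saturates.

        d(theta)/d(projected length) diverges as |theta| -> 90, so the same
        keypoint noise must produce a larger angle spread at 80 deg than at
        10 deg — the mechanism behind Grade I/II external-rotation errors.
        """
        ratio = arm_length_ratio(calibration, L)
        spreads = {}
        for phi in (10.0, 80.0):
            seq = constant_pose_trial(Movement.GLOBAL_EXTERNAL_ROTATION, phi,
                                      model, n_frames=2)
            base = seq.frames[0]
            r = np.random.default_rng(7)
            errs = []
            for _ in range(500):
                f = PoseFrame(base.keypoints.copy())
                f.keypoints[[L.elbow, L.wrist], :2] += r.normal(0, 2.0, (2, 2))
                errs.append(lower_arm_transverse_angle(f, L, ratio) - phi)
            spreads[phi] = np.std(errs)
        assert spreads[80.0] > 3.0 * spreads[10.0]


class TestMouthTouch:
    def base(self):
        return {NECK: (0, 0), MID_HIP: (0, 400), NOSE: (0, -100),
                L.shoulder: (150, 0)}

    def test_wrist_on_nose_touches(self):
        f = frame_with({**self.base(), L.wrist: (0, -100)})
        assert mouth_touch_detected(f, L)

    def test_far_wrist_does_not_touch(self):
        # two torso-lengths from both nose and shoulder
        f = frame_with({**self.base(), L.wrist: (800, 300)})
        assert not mouth_touch_detected(f, L, touch_limit=0.35)

    def test_sweep_transition_matches_brute_force(self):
        """Moving the wrist away from the nose flips touch exactly where
        both normalized distances first exceed the limit."""
        base = self.base()
        limit = 0.35
        torso = 400.0
        direction = np.array([0.6, 0.8])
        expected, got = [], []
        for step in np.arange(0.0, 1000.0, 7.0):
            wrist = np.array([0.0, -100.0]) + step * direction
            d_nose = np.linalg.norm(wrist - np.array([0.0, -100.0]))
            d_sh = np.linalg.norm(wrist - np.array([150.0, 0.0]))
            expected.append(not (d_nose > limit * torso
                                 and d_sh > limit * torso))
            f = frame_with({**base, L.wrist: tuple(wrist)})
            got.append(mouth_touch_detected(f, L, limit))
        assert got == expected
        assert True in got and False in got


class TestAngleSeries:
    def test_constant_pose_gives_constant_series(self, model):
        seq = preprocess(constant_pose_trial(Movement.GLOBAL_ABDUCTION, 75.0,
                                             model, n_frames=15))
        s = angle_series(seq, Criterion.UPPER_ARM, L)
        assert s.valid.all()
        np.testing.assert_allclose(s.values, 75.0, atol=1e-6)

    def test_degenerate_frame_masked_not_raised(self, model):
        seq = constant_pose_trial(Movement.GLOBAL_ABDUCTION, 75.0, model,
                                  n_frames=15)
        seq.frames[4].keypoints[L.elbow, :2] = seq.frames[4].keypoints[
            L.shoulder, :2]
        s = angle_series(seq, Criterion.UPPER_ARM, L)
        assert s.valid.sum() == 14
        assert not s.valid[4]

    def test_monotone_ramp_tracks_commanded_values(self, model):
        script = build_script(Movement.GLOBAL_ABDUCTION,
                              {s: 170.0 for s in ArmSide}, model,
                              n_frames=40, ramp_frames=30)
        seq = render_script(script, model, NoiseModel.none(), "ramp")
        s = angle_series(seq, Criterion.UPPER_ARM, L)
        np.testing.assert_allclose(s.values, script.angles[L][:, 0],
                                   atol=1e-6)
        assert np.all(np.diff(s.values[:30]) >= -1e-9)

    def test_transverse_requires_ratio(self, model):
        seq = constant_pose_trial(Movement.GLOBAL_EXTERNAL_ROTATION, 10.0,
                                  model, n_frames=3)
        with pytest.raises(ConfigurationError):
            angle_series(seq, Criterion.LOWER_ARM_TRANSVERSE, L)

    def test_all_degenerate_raises_empty(self, model):
        seq = constant_pose_trial(Movement.GLOBAL_ABDUCTION, 20.0, model,
                                  n_frames=3)
        for f in seq.frames:
            f.keypoints[L.elbow, 2] = 0.0
        with pytest.raises(EmptyInputError):
            angle_series(seq, Criterion.UPPER_ARM, L)


class TestInvariance:
    """Angles are invariant to translation, uniform scaling, and (for the
    in-plane angles) rotation of all image coordinates."""

    def transformed(self, frame, scale=1.0, angle=0.0, shift=(0.0, 0.0)):
        c, s = math.cos(angle), math.sin(angle)
        rot = np.array([[c, -s], [s, c]])
        kp = frame.keypoints.copy()
        kp[:, :2] = kp[:, :2] @ rot.T * scale + np.asarray(shift)
        return PoseFrame(kp, frame.frame_index)

    def test_upper_arm_and_elbow_invariant(self, model, rng):
        seq = constant_pose_trial(Movement.GLOBAL_ABDUCTION, 112.0, model,
                                  n_frames=2)
        f = seq.frames[0]
        for _ in range(25):
            g = self.transformed(f, scale=float(rng.uniform(0.1, 8)),
                                 angle=float(rng.uniform(-3, 3)),
                                 shift=tuple(rng.uniform(-500, 500, 2)))
            assert upper_arm_angle(g, L) == pytest.approx(
                upper_arm_angle(f, L), abs=1e-8)
            assert elbow_angle(g, R) == pytest.approx(
                elbow_angle(f, R), abs=1e-8)

    def test_transverse_invariant_to_translation_and_scale(
            self, model, calibration, rng):
        ratio = arm_length_ratio(calibration, L)
        seq = constant_pose_trial(Movement.GLOBAL_EXTERNAL_ROTATION, 25.0,
                                  model, n_frames=2)
        f = seq.frames[0]
        ref = lower_arm_transverse_angle(f, L, ratio)
        for _ in range(25):
            g = self.transformed(f, scale=float(rng.uniform(0.1, 8)),
                                 shift=tuple(rng.uniform(-500, 500, 2)))
            assert lower_arm_transverse_angle(g, L, ratio) == pytest.approx(
                ref, abs=1e-8)
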