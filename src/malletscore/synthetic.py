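"""Parametric 3D stick-figure generator for BODY25 keypoint sequences.

A simple kinematic arm/torso model is posed at commanded shoulder abduction,
humeral (transverse) rotation, and elbow flexion angles, then orthographically
projected to the image plane with configurable Gaussian pixel jitter,
per-keypoint confidence values, and frame dropout.  Because the projection is
orthographic and the commanded angles are exact, every criterion angle has an
analytic ground truth, which makes the whole scoring pipeline testable
without any video or pose model.

World frame (meters): +x = subject's anatomical left, +y = up,
+z = anterior (toward the camera in a frontal recording).  A frontal camera
maps world x to image x and world y to image −y (image y runs down); a rear
camera mirrors image x.  Only the MMS-relevant joints animate; the remaining
BODY25 keypoints sit at a fixed neutral template.

Conventions for the commanded arm angles, per arm:

* abduction: angle of the upper arm from the torso-down direction, in the
  coronal plane, positive away from the body (0 = arm at side, 180 =
  straight overhead);
* external rotation: azimuth of the flexion plane about the humeral axis,
  positive outward — with the elbow flexed 90° at the side this is exactly
  the forearm's transverse-plane angle (0 = forearm pointing at the camera);
* elbow flexion: deviation from a straight arm (0 = fully extended, i.e.
  interior elbow angle 180°).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import MalletScoreError
from .geometry import ArmSide
from .keypoints_io import (L_ANKLE, L_BIG_TOE, L_EAR, L_EYE, L_HEEL, L_HIP,
                           L_KNEE, L_SHOULDER, L_SMALL_TOE, MID_HIP,
                           N_KEYPOINTS, NECK, NOSE, R_ANKLE, R_BIG_TOE,
                           R_EAR, R_EYE, R_HEEL, R_HIP, R_KNEE, R_SHOULDER,
                           R_SMALL_TOE, EXPECTED_VIEW, Movement, PoseFrame,
                           PoseSequence, View)
from .scoring import GRADE_TABLE

#: lateral direction sign per side in the world frame (+x = subject's left)
_LAT = {ArmSide.LEFT: 1.0, ArmSide.RIGHT: -1.0}


@dataclass(frozen=True)
class BodyModel:
    """Segment lengths (meters) and projection scale of the stick figure.

    The defaults describe an average adult: 0.50 m torso, 0.30 m upper arm,
    0.26 m lower arm.  At 800 px/m the projected torso is 400 px tall,
    a person filling roughly half of a portrait smartphone frame.
    """

    torso_length: float = 0.50
    upper_arm: float = 0.30
    lower_arm: float = 0.26
    neck_to_nose: float = 0.12
    shoulder_width: float = 0.36
    pixels_per_meter: float = 800.0
    image_origin: tuple[float, float] = (960.0, 300.0)
    mirror: bool = False

    def __post_init__(self) -> None:
        for name in ("torso_length", "upper_arm", "lower_arm",
                     "neck_to_nose", "shoulder_width", "pixels_per_meter"):
            if not getattr(self, name) > 0:
                raise MalletScoreError(f"BodyModel.{name} must be > 0")

    @property
    def length_ratio(self) -> float:
        return self.lower_arm / self.upper_arm


@dataclass(frozen=True)
class NoiseModel:
    """Keypoint observation noise: pixel jitter, dropout, confidence."""

    jitter_sigma: float = 2.0
    dropout_prob: float = 0.01
    confidence_mean: float = 0.85
    confidence_sigma: float = 0.08
    seed: int = 0

    def __post_init__(self) -> None:
        if self.jitter_sigma < 0:
            raise MalletScoreError("jitter_sigma must be >= 0")
        if not 0.0 <= self.dropout_prob < 1.0:
            raise MalletScoreError("dropout_prob must lie in [0, 1)")

    @classmethod
    def none(cls, seed: int = 0) -> "NoiseModel":
        """Noise-free observation: exact projection, confidence 1."""
        return cls(jitter_sigma=0.0, dropout_prob=0.0, confidence_mean=1.0,
                   confidence_sigma=0.0, seed=seed)


ArmAngles = tuple[float, float, float]  # (abduction, external rotation, flexion)


@dataclass
class MovementScript:
    """Per-frame commanded joint angles for one trial.

    ``angles[side]`` is an ``(n_frames, 3)`` array of (abduction, external
    rotation, elbow flexion) in degrees.  ``lean_deg`` is a constant in-plane
    torso lean used to exercise the torso-vector referencing.
    """

    movement: Movement
    view: View
    angles: dict[ArmSide, np.ndarray]
    lean_deg: float = 0.0

    def __post_init__(self) -> None:
        n = {a.shape for a in self.angles.values()}
        if len(n) != 1 or next(iter(n))[1] != 3:
            raise MalletScoreError("per-arm angle arrays must share shape (n, 3)")
        if self.n_frames < 1:
            raise MalletScoreError("a script needs at least one frame")

    @property
    def n_frames(self) -> int:
        return next(iter(self.angles.values())).shape[0]

    def frame_angles(self, i: int) -> dict[ArmSide, ArmAngles]:
        return {side: tuple(arr[i]) for side, arr in self.angles.items()}


def _template(model: BodyModel) -> np.ndarray:
    """Neutral 3D positions of the 25 BODY25 joints (neck at the origin)."""
    T = model.torso_length
    hw = model.shoulder_width / 2.0
    j = np.zeros((N_KEYPOINTS, 3))
    j[NECK] = (0.0, 0.0, 0.0)
    j[NOSE] = (0.0, model.neck_to_nose, 0.05)
    j[MID_HIP] = (0.0, -T, 0.0)
    j[L_SHOULDER] = (hw, 0.0, 0.0)
    j[R_SHOULDER] = (-hw, 0.0, 0.0)
    j[L_EYE], j[R_EYE] = (0.03, 0.16, 0.05), (-0.03, 0.16, 0.05)
    j[L_EAR], j[R_EAR] = (0.07, 0.14, 0.0), (-0.07, 0.14, 0.0)
    j[L_HIP], j[R_HIP] = (0.10, -T, 0.0), (-0.10, -T, 0.0)
    j[L_KNEE], j[R_KNEE] = (0.10, -T - 0.40, 0.0), (-0.10, -T - 0.40, 0.0)
    j[L_ANKLE], j[R_ANKLE] = (0.10, -T - 0.80, 0.0), (-0.10, -T - 0.80, 0.0)
    j[L_HEEL], j[R_HEEL] = (0.10, -T - 0.82, -0.03), (-0.10, -T - 0.82, -0.03)
    j[L_BIG_TOE], j[R_BIG_TOE] = (0.10, -T - 0.82, 0.12), (-0.10, -T - 0.82, 0.12)
    j[L_SMALL_TOE], j[R_SMALL_TOE] = (0.14, -T - 0.82, 0.10), (-0.14, -T - 0.82, 0.10)
    return j


def _arm_chain(model: BodyModel, side: ArmSide, shoulder: np.ndarray,
               angles: ArmAngles) -> tuple[np.ndarray, np.ndarray]:
    """Forward kinematics: shoulder → elbow → wrist in world coordinates."""
    abd, ext_rot, flexion = (math.radians(a) for a in angles)
    s = _LAT[side]
    u = np.array([s * math.sin(abd), -math.cos(abd), 0.0])
    # flexion plane: start anterior, rotate about the humeral axis; positive
    # external rotation swings the forearm outward for either side
    rho = -s * ext_rot
    w = Rotation.from_rotvec(rho * u).apply(np.array([0.0, 0.0, 1.0]))
    f = math.cos(flexion) * u + math.sin(flexion) * w
    elbow = shoulder + model.upper_arm * u
    wrist = elbow + model.lower_arm * f
    return elbow, wrist


def pose_skeleton(model: BodyModel,
                  frame_angles: dict[ArmSide, ArmAngles],
                  lean_deg: float = 0.0) -> np.ndarray:
    """3D joint positions (25×3) for one frame of commanded arm angles."""
    joints = _template(model)
    for side, angles in frame_angles.items():
        shoulder = joints[side.shoulder]
        elbow, wrist = _arm_chain(model, side, shoulder, angles)
        joints[side.elbow] = elbow
        joints[side.wrist] = wrist
    if lean_deg:
        rot = Rotation.from_rotvec([0.0, 0.0, math.radians(lean_deg)])
        pivot = joints[MID_HIP].copy()
        joints = rot.apply(joints - pivot) + pivot
    return joints


def project_and_noise(joints3d: np.ndarray, model: BodyModel,
                      noise: NoiseModel, view: View = View.FRONTAL,
                      frame_index: int = 0,
                      rng: Optional[np.random.Generator] = None) -> PoseFrame:
    """Orthographic projection to a y-down pixel frame plus observation noise.

    The depth (camera) axis is dropped; a rear view mirrors image x.  Dropped
    keypoints get zeroed coordinates and confidence 0.  Deterministic for a
    given generator state.
    """
    if rng is None:
        rng = np.random.default_rng(noise.seed)
    cx, cy = model.image_origin
    x_sign = 1.0 if view is View.FRONTAL else -1.0
    if model.mirror:
        x_sign = -x_sign
    ix = x_sign * model.pixels_per_meter * joints3d[:, 0] + cx
    iy = -model.pixels_per_meter * joints3d[:, 1] + cy
    kp = np.column_stack([ix, iy, np.ones(N_KEYPOINTS)])
    if noise.jitter_sigma > 0:
        kp[:, :2] += rng.normal(0.0, noise.jitter_sigma, (N_KEYPOINTS, 2))
    if noise.confidence_sigma > 0:
        conf = rng.normal(noise.confidence_mean, noise.confidence_sigma,
                          N_KEYPOINTS)
        kp[:, 2] = np.clip(conf, 0.05, 1.0)
    else:
        kp[:, 2] = noise.confidence_mean
    if noise.dropout_prob > 0:
        drop = rng.random(N_KEYPOINTS) < noise.dropout_prob
        kp[drop] = 0.0
    return PoseFrame(kp, frame_index)


def render_script(script: MovementScript, model: BodyModel,
                  noise: NoiseModel, trial_id: str,
                  rng: Optional[np.random.Generator] = None) -> PoseSequence:
    """Pose, project, and noise every frame of a script into a PoseSequence."""
    if rng is None:
        rng = np.random.default_rng(noise.seed)
    frames = [
        project_and_noise(
            pose_skeleton(model, script.frame_angles(i), script.lean_deg),
            model, noise, script.view, i, rng)
        for i in range(script.n_frames)
    ]
    return PoseSequence(frames, script.movement, script.view, trial_id)


# ---------------------------------------------------------------------------
# movement scripting


def _smoothstep(n_ramp: int, n_total: int) -> np.ndarray:
    """C1 ramp 0→1 over n_ramp frames, then held at 1."""
    t = np.minimum(np.arange(n_total) / max(n_ramp, 1), 1.0)
    return t * t * (3.0 - 2.0 * t)


def commanded_angle(movement: Movement, grade: int) -> float:
    """Criterion angle a demonstration of ``grade`` should peak at.

    Bounded grade intervals use their midpoint; open-ended intervals use the
    printed boundary ± 10°.  Hand-to-mouth Grade I has no angle (it is the
    "not able to touch" outcome); a nominal 60° raise is returned for it.
    """
    table = GRADE_TABLE[movement]
    boundaries = list(table.boundaries)
    grades = list(table.grades_ascending)
    if movement is Movement.HAND_TO_MOUTH:
        if grade == 1:
            return 60.0
        # Grade II is open-ended above 75°; drop the duplicated top interval
        boundaries, grades = boundaries[:3], grades[:4]
    edges = [-math.inf, *boundaries, math.inf]
    idx = grades.index(grade)
    lo, hi = edges[idx], edges[idx + 1]
    if math.isinf(lo):
        return hi - 10.0
    if math.isinf(hi):
        return lo + 10.0
    return (lo + hi) / 2.0


def _aim_forearm(model: BodyModel, side: ArmSide, abd_deg: float,
                 target: np.ndarray) -> tuple[float, float]:
    """(external rotation, flexion) steering the forearm at a 3D target point."""
    s = _LAT[side]
    abd = math.radians(abd_deg)
    u = np.array([s * math.sin(abd), -math.cos(abd), 0.0])
    shoulder = np.array([s * model.shoulder_width / 2.0, 0.0, 0.0])
    elbow = shoulder + model.upper_arm * u
    d = target - elbow
    norm = np.linalg.norm(d)
    if norm < 1e-9:
        return 0.0, 90.0
    fhat = d / norm
    flexion = math.degrees(math.acos(np.clip(float(u @ fhat), -1.0, 1.0)))
    w = fhat - float(u @ fhat) * u
    wn = np.linalg.norm(w)
    if wn < 1e-9:
        return 0.0, flexion
    what = w / wn
    w0 = np.array([0.0, 0.0, 1.0])
    rho = math.atan2(float(u @ np.cross(w0, what)), float(w0 @ what))
    return -s * math.degrees(rho), flexion


def build_script(movement: Movement,
                 peak: dict[ArmSide, float],
                 model: BodyModel,
                 n_frames: int = 30,
                 ramp_frames: int = 12,
                 lean_deg: float = 0.0,
                 hold_only: bool = False) -> MovementScript:
    """Script a trial that ramps from neutral to a commanded peak and holds.

    ``peak[side]`` is the commanded criterion angle: θUA for abduction /
    hand-to-neck / hand-to-mouth, the transverse angle for external rotation,
    and the interior elbow angle θE for hand-on-spine.  External-rotation
    trials hold the commanded end-range pose for every frame (a held
    demonstration), because the trial summary is the best-achieved angle and
    a ramp through neutral would mask internally rotated end ranges.
    ``hold_only`` holds the peak pose for all movements (used for threshold
    sweeps).
    """
    movement = Movement(movement)
    view = EXPECTED_VIEW[movement]
    t = _smoothstep(ramp_frames, n_frames)
    if hold_only or movement is Movement.GLOBAL_EXTERNAL_ROTATION:
        t = np.ones(n_frames)
    angles: dict[ArmSide, np.ndarray] = {}
    nose = _template(model)[NOSE]
    neck_back = np.array([0.0, 0.03, -0.05])
    for side in ArmSide:
        a = np.zeros((n_frames, 3))
        p = peak[side]
        if movement is Movement.GLOBAL_ABDUCTION:
            a[:, 0] = p * t
        elif movement is Movement.GLOBAL_EXTERNAL_ROTATION:
            a[:, 0] = 0.0
            a[:, 1] = p * t
            a[:, 2] = 90.0
        elif movement is Movement.HAND_ON_SPINE:
            a[:, 0] = 12.0
            a[:, 1] = -90.0  # flexion plane rotated into the coronal plane, medial
            a[:, 2] = (180.0 - p) * t
        else:  # hand-to-neck / hand-to-mouth: abduct while aiming the forearm
            target = nose if movement is Movement.HAND_TO_MOUTH else neck_back
            a[:, 0] = p * t
            for i in range(n_frames):
                rot_aim, flex_aim = _aim_forearm(model, side, a[i, 0], target)
                a[i, 1] = rot_aim
                a[i, 2] = flex_aim * t[i]
        angles[side] = a
    return MovementScript(movement, view, angles, lean_deg)


def make_trial(movement: Movement, target_grade: int,
               model: Optional[BodyModel] = None,
               noise: Optional[NoiseModel] = None,
               n_frames: int = 30, seed: int = 0,
               trial_id: Optional[str] = None,
               lean_deg: float = 0.0) -> tuple[PoseSequence, dict]:
    """Generate one trial demonstrating ``target_grade`` plus its ground truth.

    The commanded criterion angle sits at the midpoint of the grade's
    interval (boundary ± 10° for open-ended intervals); both arms move
    symmetrically.  A hand-to-mouth Grade I trial raises a straight arm that
    never approaches the face, producing the "not able to touch" outcome.
    """
    movement = Movement(movement)
    if target_grade not in (1, 2, 3, 4, 5):
        raise MalletScoreError(f"target_grade must be 1..5, got {target_grade}")
    model = model or BodyModel()
    noise = noise or NoiseModel.none()
    angle = commanded_angle(movement, target_grade)
    if movement is Movement.HAND_TO_MOUTH and target_grade == 1:
        # straight-arm raise: wrist stays far from both nose and shoulder
        script = build_script(Movement.GLOBAL_ABDUCTION,
                              {s: angle for s in ArmSide}, model,
                              n_frames, lean_deg=lean_deg)
        script = replace(script, movement=movement,
                         view=EXPECTED_VIEW[movement])
    else:
        script = build_script(movement, {s: angle for s in ArmSide}, model,
                              n_frames, lean_deg=lean_deg)
    if trial_id is None:
        trial_id = f"{movement.value}_g{target_grade}_s{seed}"
    rng = np.random.default_rng(seed)
    seq = render_script(script, model, noise, trial_id, rng)
    truth = {
        "trial_id": trial_id,
        "movement": movement.value,
        "view": script.view.value,
        "grade": target_grade,
        "commanded_angle_deg": {s.value: angle for s in ArmSide},
        "n_frames": n_frames,
        "seed": seed,
    }
    return seq, truth


def constant_pose_trial(movement: Movement,
                        angle: float | dict[ArmSide, float],
                        model: Optional[BodyModel] = None,
                        n_frames: int = 15,
                        trial_id: str = "sweep") -> PoseSequence:
    """Noise-free trial holding a commanded criterion angle in every frame.

    Used for threshold sweeps: with a held pose the Savitzky–Golay filter is
    exact and the recovered summary angle equals the commanded angle to
    floating-point precision.
    """
    model = model or BodyModel()
    if not isinstance(angle, dict):
        angle = {s: angle for s in ArmSide}
    script = build_script(movement, angle, model, n_frames, hold_only=True)
    return render_script(script, model, NoiseModel.none(), trial_id)


def make_grid(model: Optional[BodyModel] = None,
              noise: Optional[NoiseModel] = None,
              n_frames: int = 30, seed: int = 0,
              movements: Optional[list[Movement]] = None,
              ) -> list[tuple[PoseSequence, dict]]:
    """The full movement × grade demonstration grid (5 × 5 by default)."""
    model = model or BodyModel()
    movements = movements or list(Movement)
    out = []
    for m, movement in enumerate(movements):
        for grade in (1, 2, 3, 4, 5):
            trial_seed = seed * 100 + m * 10 + grade
            out.append(make_trial(movement, grade, model, noise, n_frames,
                                  seed=trial_seed))
    return out
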