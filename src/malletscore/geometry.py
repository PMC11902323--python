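"""Criterion angles from 2D keypoints.

Three angles drive the automated Modified Mallet Score:

* the upper-arm angle θUA between the torso vector and the shoulder→elbow
  vector (global abduction, hand-to-neck, hand-to-mouth);
* the interior elbow angle θE between elbow→shoulder and elbow→wrist
  (hand-on-spine, rear view);
* the lower-arm transverse-plane angle θLATP (global external rotation),
  which cannot be read directly from a frontal 2D view.  It is estimated
  from the ratio of the forearm's projected image length to its true length,
  the latter inferred from an upper-arm/lower-arm length ratio calibrated on
  the same session's global-abduction trial (where the whole arm lies in the
  image plane):

      θLATP = ±(90° − arccos(l_lower_projected / l_lower)),

  positive when the forearm points outward (external rotation), negative
  inward.  The sign is taken from the wrist's mediolateral image position
  relative to the elbow.

Angles are computed with atan2 of the cross/dot products, which is
algebraically identical to the arccos form but better conditioned near 0°
and 180°.  All angles are reported in degrees.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from enum import Enum

import numpy as np

from .errors import (CalibrationError, ConfigurationError,
                     DegenerateGeometryError, EmptyInputError,
                     MissingKeypointError)
from .keypoints_io import (KEYPOINT_NAMES, L_ELBOW, L_SHOULDER, L_WRIST,
                           MID_HIP, NECK, NOSE, R_ELBOW, R_SHOULDER, R_WRIST,
                           Movement, PoseFrame, PoseSequence)
from .preprocessing import torso_vector

logger = logging.getLogger(__name__)

DEFAULT_TOUCH_LIMIT = 0.35  # fraction of torso length, see mouth_touch_detected


class ArmSide(str, Enum):
    """Left/right arm with its fixed BODY25 index mapping."""

    LEFT = "left"
    RIGHT = "right"

    @property
    def shoulder(self) -> int:
        return L_SHOULDER if self is ArmSide.LEFT else R_SHOULDER

    @property
    def elbow(self) -> int:
        return L_ELBOW if self is ArmSide.LEFT else R_ELBOW

    @property
    def wrist(self) -> int:
        return L_WRIST if self is ArmSide.LEFT else R_WRIST


class Criterion(str, Enum):
    UPPER_ARM = "upper_arm"                      # θUA
    ELBOW = "elbow"                              # θE
    LOWER_ARM_TRANSVERSE = "lower_arm_transverse"  # θLATP


#: Representable range per criterion, degrees.
CRITERION_RANGE = {
    Criterion.UPPER_ARM: (0.0, 180.0),
    Criterion.ELBOW: (0.0, 180.0),
    Criterion.LOWER_ARM_TRANSVERSE: (-90.0, 90.0),
}


@dataclass
class AngleSeries:
    """Per-frame criterion angle (degrees) with a validity mask."""

    values: np.ndarray
    valid: np.ndarray
    criterion: Criterion
    side: ArmSide

    def valid_values(self) -> np.ndarray:
        return self.values[self.valid]


@dataclass
class ArmLengthRatio:
    """Lower-arm / upper-arm length ratio from an abduction calibration trial."""

    ratio: float
    side: ArmSide
    n_frames_used: int

    def __post_init__(self) -> None:
        if not self.ratio > 0:
            raise CalibrationError(f"arm length ratio must be > 0, got {self.ratio}")
        if not 0.6 <= self.ratio <= 1.3:
            logger.warning(
                "arm length ratio %.3f (%s) is outside the typical human "
                "range [0.6, 1.3]; check the calibration trial",
                self.ratio, self.side.value)


def _require(frame: PoseFrame, indices: tuple[int, ...],
             validity: np.ndarray | None) -> None:
    for idx in indices:
        missing = (not validity[idx]) if validity is not None else frame.is_missing(idx)
        if missing:
            name = KEYPOINT_NAMES.get(idx, f"keypoint {idx}")
            raise MissingKeypointError(
                f"{name} (KP{idx}) missing in frame {frame.frame_index}")


def _angle_between(v1: np.ndarray, v2: np.ndarray) -> float:
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 < 1e-12 or n2 < 1e-12:
        raise DegenerateGeometryError(
            "zero-magnitude segment vector (coincident keypoints)")
    cross = v1[0] * v2[1] - v1[1] * v2[0]
    dot = float(np.dot(v1, v2))
    return math.degrees(math.atan2(abs(cross), dot))


def upper_arm_angle(frame: PoseFrame, side: ArmSide,
                    validity: np.ndarray | None = None) -> float:
    """θUA: angle between the torso vector and the shoulder→elbow vector.

    0° means the arm hangs along the torso; 180° is straight overhead.
    """
    _require(frame, (NECK, MID_HIP, side.shoulder, side.elbow), validity)
    vt = torso_vector(frame, validity).as_array()
    upper = frame.xy[side.elbow] - frame.xy[side.shoulder]
    return _angle_between(vt, upper)


def elbow_angle(frame: PoseFrame, side: ArmSide,
                validity: np.ndarray | None = None) -> float:
    """θE: interior elbow angle; 180° is a fully extended arm."""
    _require(frame, (side.shoulder, side.elbow, side.wrist), validity)
    to_shoulder = frame.xy[side.shoulder] - frame.xy[side.elbow]
    to_wrist = frame.xy[side.wrist] - frame.xy[side.elbow]
    return _angle_between(to_shoulder, to_wrist)


def arm_length_ratio(calibration_seq: PoseSequence, side: ArmSide) -> ArmLengthRatio:
    """Mean per-frame forearm/upper-arm length ratio over a global-abduction trial.

    During global abduction the whole arm lies in the image plane, so pixel
    segment lengths are proportional to true lengths.  The per-frame ratios
    ||elbow→wrist|| / ||shoulder→elbow|| are averaged over all frames where
    the arm is fully detected.
    """
    if calibration_seq.movement is not Movement.GLOBAL_ABDUCTION:
        logger.warning(
            "calibration trial %s is %s, not a global-abduction trial; the "
            "arm-length ratio assumes the arm stays in the image plane",
            calibration_seq.trial_id, calibration_seq.movement.value)
    arr = calibration_seq.as_array()
    mask = calibration_seq.valid_mask()
    s, e, w = side.shoulder, side.elbow, side.wrist
    ok = mask[:, s] & mask[:, e] & mask[:, w]
    upper = np.linalg.norm(arr[:, e, :2] - arr[:, s, :2], axis=1)
    lower = np.linalg.norm(arr[:, w, :2] - arr[:, e, :2], axis=1)
    ok &= upper > 1e-9
    if not ok.any():
        raise CalibrationError(
            f"no frame in {calibration_seq.trial_id!r} has a fully detected "
            f"{side.value} arm; cannot calibrate the arm-length ratio")
    ratio = float(np.mean(lower[ok] / upper[ok]))
    return ArmLengthRatio(ratio, side, int(ok.sum()))


def lower_arm_transverse_angle(frame: PoseFrame, side: ArmSide,
                               ratio: ArmLengthRatio,
                               mirror: bool = False,
                               validity: np.ndarray | None = None) -> float:
    """θLATP: transverse-plane forearm angle from the projected-length ratio.

    0° = forearm pointing at the camera (parallel to the sagittal plane);
    positive = external (outward) rotation; negative = internal.  The ratio
    l_projected/l_lower is clamped to [0, 1] before arccos since keypoint
    noise routinely pushes it above 1.

    The sign is taken from the wrist's mediolateral image position relative
    to the elbow: in an ordinary (non-mirrored) frontal view the subject's
    right is on the image left, so "outward" for the right arm means wrist
    left of (image-x below) the elbow.  Set ``mirror=True`` for selfie-mode
    footage.
    """
    _require(frame, (side.shoulder, side.elbow, side.wrist), validity)
    l_upper = float(np.linalg.norm(frame.xy[side.elbow] - frame.xy[side.shoulder]))
    if l_upper < 1e-12:
        raise DegenerateGeometryError(
            "coincident shoulder and elbow keypoints; cannot scale forearm length")
    l_lower = l_upper * ratio.ratio
    if l_lower <= 0:
        raise CalibrationError(f"non-positive true forearm length {l_lower}")
    l_projected = float(np.linalg.norm(frame.xy[side.wrist] - frame.xy[side.elbow]))
    c = min(max(l_projected / l_lower, 0.0), 1.0)
    magnitude = 90.0 - math.degrees(math.acos(c))
    # outward = image +x for the subject's left arm in a frontal view
    outward = 1.0 if side is ArmSide.LEFT else -1.0
    if mirror:
        outward = -outward
    dx = float(frame.xy[side.wrist, 0] - frame.xy[side.elbow, 0])
    sign = 1.0 if dx * outward >= 0 else -1.0
    return sign * magnitude


def wrist_nose_distance(frame: PoseFrame, side: ArmSide,
                        validity: np.ndarray | None = None) -> float:
    """Image-plane wrist–nose distance (pixels)."""
    _require(frame, (NOSE, side.wrist), validity)
    return float(np.linalg.norm(frame.xy[side.wrist] - frame.xy[NOSE]))


def mouth_touch_detected(frame: PoseFrame, side: ArmSide,
                         touch_limit: float = DEFAULT_TOUCH_LIMIT,
                         validity: np.ndarray | None = None) -> bool:
    """Hand-to-mouth touch test.

    The movement counts as "not able to touch" only when BOTH the wrist–nose
    and the wrist–shoulder distances exceed ``touch_limit`` times the torso
    length (the torso is the body-scale normalizer, so the rule is
    scale-invariant).
    """
    _require(frame, (NOSE, side.shoulder, side.wrist, NECK, MID_HIP), validity)
    scale = torso_vector(frame, validity).magnitude
    if scale < 1e-12:
        raise DegenerateGeometryError("zero-length torso; cannot normalize distances")
    limit = touch_limit * scale
    d_nose = np.linalg.norm(frame.xy[side.wrist] - frame.xy[NOSE])
    d_shoulder = np.linalg.norm(frame.xy[side.wrist] - frame.xy[side.shoulder])
    return not (d_nose > limit and d_shoulder > limit)


#: Criterion used by each movement (Algorithmic MMS sheet).
MOVEMENT_CRITERION = {
    Movement.GLOBAL_ABDUCTION: Criterion.UPPER_ARM,
    Movement.GLOBAL_EXTERNAL_ROTATION: Criterion.LOWER_ARM_TRANSVERSE,
    Movement.HAND_TO_NECK: Criterion.UPPER_ARM,
    Movement.HAND_ON_SPINE: Criterion.ELBOW,
    Movement.HAND_TO_MOUTH: Criterion.UPPER_ARM,
}


def angle_series(seq: PoseSequence, criterion: Criterion, side: ArmSide,
                 ratio: ArmLengthRatio | None = None,
                 mirror: bool = False) -> AngleSeries:
    """Per-frame criterion angle over a preprocessed sequence.

    Frames with missing keypoints or degenerate geometry are marked invalid
    in the mask rather than raised, so one bad frame does not sink a trial.
    """
    criterion = Criterion(criterion)
    if criterion is Criterion.LOWER_ARM_TRANSVERSE and ratio is None:
        raise ConfigurationError(
            "lower_arm_transverse requires an arm-length ratio from a "
            "global-abduction calibration trial")
    mask = seq.valid_mask()
    n = seq.n_frames
    values = np.full(n, np.nan)
    valid = np.zeros(n, dtype=bool)
    for i, frame in enumerate(seq.frames):
        v = mask[i]
        try:
            if criterion is Criterion.UPPER_ARM:
                values[i] = upper_arm_angle(frame, side, v)
            elif criterion is Criterion.ELBOW:
                values[i] = elbow_angle(frame, side, v)
            else:
                values[i] = lower_arm_transverse_angle(frame, side, ratio,
                                                       mirror, v)
            valid[i] = True
        except (MissingKeypointError, DegenerateGeometryError):
            pass
    if not valid.any():
        raise EmptyInputError(
            f"no frame of {seq.trial_id!r} yields a valid "
            f"{criterion.value} angle for the {side.value} arm")
    return AngleSeries(values, valid, criterion, side)
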