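"""Map criterion angles to Modified Mallet Score grades I–V.

The Algorithmic MMS sheet quantifies each movement's five grades as angle
intervals:

================  =========  ==========  ==========  ==========  =========
movement          Grade I    Grade II    Grade III   Grade IV    Grade V
================  =========  ==========  ==========  ==========  =========
global abduction  θ ≤ 15     (15, 30]    (30, 90]    (90, 150]   θ > 150
ext. rotation     θ ≤ −40    (−40, 0]    (0, 20]     (20, 40]    θ > 40
hand to neck      θ ≤ 30     (30, 50]    (50, 80]    (80, 110]   θ > 110
hand on spine     θ > 155    (115, 155]  (95, 115]   (70, 95]    θ ≤ 70
hand to mouth     no touch   θ > 75      (45, 75]    (30, 45]    θ ≤ 30
================  =========  ==========  ==========  ==========  =========

(θ is θUA for abduction / hand-to-neck / hand-to-mouth, θLATP for external
rotation, θE for hand-on-spine; I = no function, V = normal.)  Where the
printed sheet leaves a single boundary value unassigned between two strict
inequalities, the boundary joins the open-ended extreme interval, so the
five intervals partition the criterion's range.

Grade V additionally demands symmetry: a trial is scored V on both arms only
when at least one arm's angle meets the Grade V condition and the two arms'
summary angles differ by no more than 15°; an arm whose angle is in the V
range but whose contralateral angle differs by more is capped at Grade IV
("normal and symmetric to other arm").  Hand-to-mouth trials where the wrist
approaches neither the nose nor the shoulder are "not able to touch" and
scored Grade I regardless of angle.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .config import RunConfig
from .errors import (ConfigurationError, DomainError, EmptyInputError)
from .geometry import (CRITERION_RANGE, MOVEMENT_CRITERION, AngleSeries,
                       ArmSide, Criterion, angle_series, arm_length_ratio,
                       mouth_touch_detected, wrist_nose_distance)
from .keypoints_io import Movement, PoseSequence
from .preprocessing import preprocess

logger = logging.getLogger(__name__)

ROMAN = {1: "I", 2: "II", 3: "III", 4: "IV", 5: "V"}

#: Sub-micro-degree differences carry no physical meaning; angles are rounded
#: to this many decimals before threshold comparison so floating-point noise
#: cannot flip a grade at an exact interval boundary.
_ANGLE_DECIMALS = 6


@dataclass(frozen=True)
class MalletGrade:
    """One MMS grade, 1 (no function) … 5 (normal)."""

    value: int

    def __post_init__(self) -> None:
        if self.value not in ROMAN:
            raise ValueError(f"grade must be 1..5, got {self.value}")

    @property
    def roman(self) -> str:
        return ROMAN[self.value]

    def __int__(self) -> int:
        return self.value


@dataclass(frozen=True)
class GradeThresholds:
    """Grade intervals for one movement along the ascending angle axis.

    ``boundaries`` are the four interior interval edges in ascending angle
    order; ``grades_ascending`` lists the grade of each of the five
    half-open intervals (-inf, b0], (b0, b1], ..., (b3, +inf) in the same
    order.  ``higher_is_better`` records the functional direction.
    """

    movement: Movement
    criterion: Criterion
    boundaries: tuple[float, float, float, float]
    grades_ascending: tuple[int, int, int, int, int]
    higher_is_better: bool

    def __post_init__(self) -> None:
        if list(self.boundaries) != sorted(self.boundaries):
            raise ValueError("boundaries must be strictly ascending")


GRADE_TABLE: dict[Movement, GradeThresholds] = {
    Movement.GLOBAL_ABDUCTION: GradeThresholds(
        Movement.GLOBAL_ABDUCTION, Criterion.UPPER_ARM,
        (15.0, 30.0, 90.0, 150.0), (1, 2, 3, 4, 5), True),
    Movement.GLOBAL_EXTERNAL_ROTATION: GradeThresholds(
        Movement.GLOBAL_EXTERNAL_ROTATION, Criterion.LOWER_ARM_TRANSVERSE,
        (-40.0, 0.0, 20.0, 40.0), (1, 2, 3, 4, 5), True),
    Movement.HAND_TO_NECK: GradeThresholds(
        Movement.HAND_TO_NECK, Criterion.UPPER_ARM,
        (30.0, 50.0, 80.0, 110.0), (1, 2, 3, 4, 5), True),
    Movement.HAND_ON_SPINE: GradeThresholds(
        Movement.HAND_ON_SPINE, Criterion.ELBOW,
        (70.0, 95.0, 115.0, 155.0), (5, 4, 3, 2, 1), False),
    # hand-to-mouth Grade I is reachable only through the touch rule; on the
    # angle axis the four intervals II..V share grade 2 above 75°.
    Movement.HAND_TO_MOUTH: GradeThresholds(
        Movement.HAND_TO_MOUTH, Criterion.UPPER_ARM,
        (30.0, 45.0, 75.0, 180.0), (5, 4, 3, 2, 2), False),
}


def grade_from_angle(movement: Movement, angle: float,
                     touch: Optional[bool] = None) -> MalletGrade:
    """The unique grade whose interval contains ``angle``.

    For hand-to-mouth, ``touch`` is required; ``touch=False`` returns
    Grade I ("not able to touch") regardless of angle.
    """
    movement = Movement(movement)
    table = GRADE_TABLE[movement]
    if movement is Movement.HAND_TO_MOUTH:
        if touch is None:
            raise ConfigurationError(
                "hand-to-mouth grading requires the touch flag")
        if not touch:
            return MalletGrade(1)
    if not np.isfinite(angle):
        raise DomainError(f"angle must be finite, got {angle}")
    lo, hi = CRITERION_RANGE[table.criterion]
    if not lo - 1e-6 <= angle <= hi + 1e-6:
        raise DomainError(
            f"angle {angle:.3f}° outside the {table.criterion.value} "
            f"range [{lo}, {hi}]")
    a = round(float(angle), _ANGLE_DECIMALS)
    idx = int(sum(a > b for b in table.boundaries))
    return MalletGrade(table.grades_ascending[idx])


def meets_grade_v(movement: Movement, angle: float,
                  touch: Optional[bool] = None) -> bool:
    """Whether an angle satisfies the movement's Grade V condition."""
    return grade_from_angle(movement, angle, touch).value == 5


def summarize_angle(series: AngleSeries, movement: Movement,
                    wrist_nose_dist: Optional[np.ndarray] = None) -> float:
    """Reduce a per-frame angle series to the trial's summary angle.

    MMS scores the best movement the patient achieves, so the summary is the
    best value in the movement's functional direction: max θUA for abduction
    and hand-to-neck, max θLATP for external rotation, min θE for
    hand-on-spine.  For hand-to-mouth the summary is θUA at the frame where
    the wrist comes closest to the nose (the touch attempt), which requires
    the per-frame wrist–nose distances.
    """
    movement = Movement(movement)
    if not series.valid.any():
        raise EmptyInputError("angle series has no valid frame to summarize")
    vals = series.values
    valid = series.valid
    if movement is Movement.HAND_TO_MOUTH:
        if wrist_nose_dist is None:
            raise ConfigurationError(
                "hand-to-mouth summary needs per-frame wrist–nose distances")
        d = np.where(valid & np.isfinite(wrist_nose_dist), wrist_nose_dist,
                     np.inf)
        return float(vals[int(np.argmin(d))])
    if movement is Movement.HAND_ON_SPINE:
        return float(np.min(vals[valid]))
    return float(np.max(vals[valid]))


def apply_symmetry_rule(left_angle: float, right_angle: float,
                        left_grade: MalletGrade, right_grade: MalletGrade,
                        movement: Movement,
                        threshold_deg: float = 15.0,
                        ) -> tuple[MalletGrade, MalletGrade, bool]:
    """The 15° Grade V symmetry rule, symmetric in left/right.

    Grade V means "normal and symmetric to the other arm": when at least one
    arm's angle meets the Grade V condition and the two summary angles differ
    by no more than ``threshold_deg``, both arms are scored V; when they
    differ by more, any arm holding a Grade V is capped at IV and the other
    arm keeps its grade.  Grades below the IV/V boundary are never changed.
    """
    movement = Movement(movement)
    diff = round(abs(left_angle - right_angle), _ANGLE_DECIMALS)
    any_v = 5 in (left_grade.value, right_grade.value)
    if not any_v:
        return left_grade, right_grade, False
    if diff <= threshold_deg:
        return MalletGrade(5), MalletGrade(5), True
    cap = lambda g: MalletGrade(4) if g.value == 5 else g
    return cap(left_grade), cap(right_grade), False


@dataclass
class ArmScore:
    summary_angle: float
    grade: MalletGrade
    touch: Optional[bool] = None  # hand-to-mouth only

    def to_dict(self) -> dict:
        d = {"summary_angle_deg": round(self.summary_angle, 3),
             "grade": self.grade.value, "grade_roman": self.grade.roman}
        if self.touch is not None:
            d["touch"] = self.touch
        return d


@dataclass
class TrialScore:
    """Per-arm MMS grade for one movement trial."""

    trial_id: str
    movement: Movement
    arms: dict[ArmSide, ArmScore]
    symmetry_applied: bool
    angle_difference: float
    flags: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "trial_id": self.trial_id,
            "movement": self.movement.value,
            "arms": {side.value: score.to_dict()
                     for side, score in self.arms.items()},
            "symmetry_applied": self.symmetry_applied,
            "angle_difference_deg": round(self.angle_difference, 3),
            "flags": self.flags,
        }


def score_trial(seq: PoseSequence,
                calibration: Optional[PoseSequence] = None,
                cfg: Optional[RunConfig] = None) -> TrialScore:
    """Score one movement trial end to end.

    Runs gating/smoothing, computes the per-frame criterion angle for each
    arm, reduces to a summary angle, grades against the Algorithmic MMS
    sheet, and applies the Grade V symmetry rule.  External rotation
    requires the session's global-abduction ``calibration`` trial for the
    arm-length ratio.  Deterministic: scoring the same sequence twice yields
    identical results.
    """
    cfg = cfg or RunConfig()
    movement = seq.movement
    criterion = MOVEMENT_CRITERION[movement]
    flags: list[str] = []

    pre = preprocess(seq, cfg.smoothing)
    calib_pre = None
    if movement is Movement.GLOBAL_EXTERNAL_ROTATION:
        if calibration is None:
            raise ConfigurationError(
                "global external rotation needs a global-abduction "
                "calibration trial for the arm-length ratio")
        calib_pre = preprocess(calibration, cfg.smoothing)

    summaries: dict[ArmSide, float] = {}
    touches: dict[ArmSide, Optional[bool]] = {}
    grades: dict[ArmSide, MalletGrade] = {}
    for side in ArmSide:
        ratio = (arm_length_ratio(calib_pre, side)
                 if calib_pre is not None else None)
        series = angle_series(pre, criterion, side, ratio, mirror=cfg.mirror)
        wn = None
        touch: Optional[bool] = None
        if movement is Movement.HAND_TO_MOUTH:
            mask = pre.valid_mask()
            wn = np.full(pre.n_frames, np.inf)
            for i, frame in enumerate(pre.frames):
                try:
                    wn[i] = wrist_nose_distance(frame, side, mask[i])
                except Exception:
                    pass
        summary = summarize_angle(series, movement, wn)
        if movement is Movement.HAND_TO_MOUTH:
            attempt = int(np.argmin(wn))
            touch = mouth_touch_detected(pre.frames[attempt], side,
                                         cfg.touch_limit,
                                         pre.valid_mask()[attempt])
        summaries[side] = summary
        touches[side] = touch
        grades[side] = grade_from_angle(movement, summary, touch)

    diff = abs(summaries[ArmSide.LEFT] - summaries[ArmSide.RIGHT])
    symmetry_applied = False
    skip_symmetry = (movement is Movement.HAND_TO_MOUTH
                     and not all(touches[s] for s in ArmSide))
    if skip_symmetry:
        flags.append("symmetry-skipped-touch-failure")
    else:
        lg, rg, symmetry_applied = apply_symmetry_rule(
            summaries[ArmSide.LEFT], summaries[ArmSide.RIGHT],
            grades[ArmSide.LEFT], grades[ArmSide.RIGHT],
            movement, cfg.symmetry_threshold_deg)
        grades[ArmSide.LEFT], grades[ArmSide.RIGHT] = lg, rg

    if movement is Movement.HAND_TO_NECK and cfg.hand_to_neck_coupling:
        # 2D keypoints cannot tell hand-in-front from hand-behind-head, so the
        # coupled mode assigns both arms the lower (conservative) grade.
        low = min(grades.values(), key=lambda g: g.value)
        grades = {side: low for side in grades}
        flags.append("hand-to-neck-coupled")

    arms = {side: ArmScore(summaries[side], grades[side], touches[side])
            for side in ArmSide}
    return TrialScore(seq.trial_id, movement, arms, symmetry_applied, diff,
                      flags)
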