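"""Read, validate, and write OpenPose BODY25 keypoint sequences.

The on-disk interface is the per-frame JSON dialect that OpenPose (>=1.7.0)
writes: a top-level ``"people"`` list in which each person carries a
``"pose_keypoints_2d"`` entry of 75 floats laid out as
``x0, y0, c0, ..., x24, y24, c24``.  One file per video frame; the frame
number is embedded in the file name (``<prefix>_000000000042_keypoints.json``).

Coordinates are image pixels, x rightward, y downward.  A keypoint with
confidence 0 is treated as missing; its x, y are undefined.  All downstream
math is scale-invariant, so coordinates are kept in native pixel units.
"""

from __future__ import annotations

import json
import re
import zipfile
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from .errors import EmptyInputError, MalletScoreError, ParseError

N_KEYPOINTS = 25

# BODY25 keypoint ids (OpenPose BODY-25 keypoint legend).
NOSE = 0
NECK = 1
R_SHOULDER, R_ELBOW, R_WRIST = 2, 3, 4
L_SHOULDER, L_ELBOW, L_WRIST = 5, 6, 7
MID_HIP = 8
R_HIP, R_KNEE, R_ANKLE = 9, 10, 11
L_HIP, L_KNEE, L_ANKLE = 12, 13, 14
R_EYE, L_EYE, R_EAR, L_EAR = 15, 16, 17, 18
L_BIG_TOE, L_SMALL_TOE, L_HEEL = 19, 20, 21
R_BIG_TOE, R_SMALL_TOE, R_HEEL = 22, 23, 24

KEYPOINT_NAMES = {
    NOSE: "nose", NECK: "neck",
    R_SHOULDER: "right_shoulder", R_ELBOW: "right_elbow", R_WRIST: "right_wrist",
    L_SHOULDER: "left_shoulder", L_ELBOW: "left_elbow", L_WRIST: "left_wrist",
    MID_HIP: "mid_hip",
}


class Movement(str, Enum):
    """The five Modified Mallet Score movements."""

    GLOBAL_ABDUCTION = "global_abduction"
    GLOBAL_EXTERNAL_ROTATION = "global_external_rotation"
    HAND_TO_NECK = "hand_to_neck"
    HAND_ON_SPINE = "hand_on_spine"
    HAND_TO_MOUTH = "hand_to_mouth"


class View(str, Enum):
    FRONTAL = "frontal"
    REAR = "rear"


#: Hand-on-spine is recorded rear-facing so the hands stay visible; every
#: other movement is recorded from the front.
EXPECTED_VIEW = {
    Movement.GLOBAL_ABDUCTION: View.FRONTAL,
    Movement.GLOBAL_EXTERNAL_ROTATION: View.FRONTAL,
    Movement.HAND_TO_NECK: View.FRONTAL,
    Movement.HAND_ON_SPINE: View.REAR,
    Movement.HAND_TO_MOUTH: View.FRONTAL,
}


@dataclass
class PoseFrame:
    """One video frame's 25 BODY25 keypoints.

    ``keypoints`` is a ``(25, 3)`` float array of ``(x, y, confidence)`` rows
    indexed by BODY25 id.  Confidence lies in [0, 1]; confidence 0 marks a
    missing keypoint.
    """

    keypoints: np.ndarray
    frame_index: int = 0

    def __post_init__(self) -> None:
        kp = np.asarray(self.keypoints, dtype=float)
        if kp.shape != (N_KEYPOINTS, 3):
            raise ValueError(f"expected (25, 3) keypoint array, got {kp.shape}")
        self.keypoints = kp

    @property
    def xy(self) -> np.ndarray:
        return self.keypoints[:, :2]

    @property
    def confidence(self) -> np.ndarray:
        return self.keypoints[:, 2]

    def is_missing(self, idx: int) -> bool:
        return self.keypoints[idx, 2] <= 0.0

    @property
    def all_missing(self) -> bool:
        return bool(np.all(self.confidence <= 0.0))

    def copy(self) -> "PoseFrame":
        return PoseFrame(self.keypoints.copy(), self.frame_index)


@dataclass
class PoseSequence:
    """Ordered frames for one movement trial.

    ``validity`` is an optional ``(n_frames, 25)`` boolean mask attached by
    :func:`malletscore.preprocessing.gate_and_fill`; when absent, a keypoint
    sample counts as valid iff its confidence is positive.
    """

    frames: list[PoseFrame]
    movement: Movement
    view: View
    trial_id: str = ""
    validity: Optional[np.ndarray] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if not self.frames:
            raise EmptyInputError("PoseSequence requires at least one frame")
        idx = [f.frame_index for f in self.frames]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("frame_index must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def as_array(self) -> np.ndarray:
        """Stack keypoints into an ``(n_frames, 25, 3)`` array."""
        return np.stack([f.keypoints for f in self.frames])

    def frame_indices(self) -> np.ndarray:
        return np.array([f.frame_index for f in self.frames])

    def valid_mask(self) -> np.ndarray:
        """``(n_frames, 25)`` validity; falls back to confidence > 0."""
        if self.validity is not None:
            return self.validity
        return self.as_array()[:, :, 2] > 0.0

    def replace_frames(self, coords: np.ndarray,
                       validity: Optional[np.ndarray] = None) -> "PoseSequence":
        """New sequence with coordinates replaced, confidences kept."""
        arr = self.as_array()
        out = arr.copy()
        out[:, :, :2] = coords
        frames = [PoseFrame(out[i], f.frame_index)
                  for i, f in enumerate(self.frames)]
        if validity is None:
            validity = self.validity
        return PoseSequence(frames, self.movement, self.view, self.trial_id,
                            validity)


_FRAME_NUM_RE = re.compile(r"(\d+)(?=_keypoints\.json$|\.json$)")


def _frame_number(name: str) -> int:
    m = _FRAME_NUM_RE.search(name)
    if m is None:
        # fall back to the last run of digits anywhere in the name
        runs = re.findall(r"\d+", name)
        if not runs:
            raise ParseError(f"cannot find a frame number in file name {name!r}")
        return int(runs[-1])
    return int(m.group(1))


def _parse_frame_json(text: str, name: str, person_index: int,
                      frame_index: int) -> PoseFrame:
    try:
        record = json.loads(text)
    except json.JSONDecodeError as exc:
        raise ParseError(f"malformed JSON in {name}: {exc}") from exc
    people = record.get("people", [])
    if not people:
        return PoseFrame(np.zeros((N_KEYPOINTS, 3)), frame_index)
    if person_index >= len(people) or person_index < 0:
        raise IndexError(
            f"person_index {person_index} out of range in {name} "
            f"({len(people)} people detected)")
    flat = people[person_index].get("pose_keypoints_2d")
    if flat is None or len(flat) != 3 * N_KEYPOINTS:
        raise ParseError(
            f"{name}: 'pose_keypoints_2d' must hold {3 * N_KEYPOINTS} numbers")
    kp = np.asarray(flat, dtype=float).reshape(N_KEYPOINTS, 3)
    return PoseFrame(kp, frame_index)


def read_openpose_sequence(source: str | Path, movement: Movement,
                           person_index: int = 0,
                           view: Optional[View] = None,
                           trial_id: Optional[str] = None) -> PoseSequence:
    """Assemble a movement trial from a directory (or .zip) of frame files.

    Frames are ordered by the numeric suffix of their file names; gaps in the
    numbering are preserved (time is never resampled).  A frame file with no
    detected person yields an all-missing frame so the trial keeps its length.
    """
    source = Path(source)
    movement = Movement(movement)
    if view is None:
        view = EXPECTED_VIEW[movement]
    if trial_id is None:
        trial_id = source.stem

    def frame_files(all_names: list[str]) -> list[str]:
        # prefer OpenPose's *_keypoints.json naming; fall back to any .json
        kp = [n for n in all_names if n.endswith("_keypoints.json")]
        return sorted(kp or all_names)

    if source.is_dir():
        names = frame_files([p.name for p in source.glob("*.json")])
        reader = lambda n: (source / n).read_text()
    elif source.suffix == ".zip" and source.is_file():
        zf = zipfile.ZipFile(source)
        names = frame_files([n for n in zf.namelist() if n.endswith(".json")])
        reader = lambda n: zf.read(n).decode()
    else:
        raise EmptyInputError(f"source {source} is not a directory or .zip")

    if not names:
        raise EmptyInputError(f"no keypoint JSON files found in {source}")

    numbered = sorted((( _frame_number(n), n) for n in names))
    frames = [_parse_frame_json(reader(n), n, person_index, num)
              for num, n in numbered]
    return PoseSequence(frames, movement, View(view), trial_id)


def write_openpose_sequence(seq: PoseSequence, dest: str | Path) -> list[Path]:
    """Write one OpenPose-dialect JSON file per frame; returns the manifest.

    Round trip through :func:`read_openpose_sequence` is the identity on
    finite keypoint values.  An all-missing frame is written as a person
    record of 75 zeros, preserving the missing flag.
    """
    if not seq.frames:
        raise EmptyInputError("refusing to write an empty sequence")
    dest = Path(dest)
    try:
        dest.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise MalletScoreError(f"cannot create destination {dest}: {exc}") from exc
    written = []
    for frame in seq.frames:
        record = {
            "version": 1.3,
            "people": [{
                "person_id": [-1],
                "pose_keypoints_2d": [float(v) for v in frame.keypoints.ravel()],
            }],
        }
        path = dest / f"{seq.trial_id or 'trial'}_{frame.frame_index:012d}_keypoints.json"
        path.write_text(json.dumps(record))
        written.append(path)
    return written


@dataclass
class ValidationIssue:
    code: str
    message: str


def validate_sequence(seq: PoseSequence,
                      smoothing_window: int = 13,
                      missing_warn_fraction: float = 0.5) -> list[ValidationIssue]:
    """Report data-quality issues without mutating the sequence.

    Checks per-keypoint missing fractions, whether the trial is long enough
    for the configured smoothing window, and movement/view consistency.
    """
    issues: list[ValidationIssue] = []
    arr = seq.as_array()
    missing_frac = np.mean(arr[:, :, 2] <= 0.0, axis=0)
    for idx in np.nonzero(missing_frac > missing_warn_fraction)[0]:
        name = KEYPOINT_NAMES.get(int(idx), f"keypoint {int(idx)}")
        issues.append(ValidationIssue(
            "missing-data",
            f"{name} missing in {missing_frac[idx]:.0%} of frames"))
    if seq.n_frames < smoothing_window:
        issues.append(ValidationIssue(
            "short-sequence",
            f"fewer than {smoothing_window} frames; smoothing window cannot "
            f"be applied as configured"))
    expected = EXPECTED_VIEW[seq.movement]
    if seq.view != expected:
        issues.append(ValidationIssue(
            "view-mismatch",
            f"{seq.movement.value} is recorded from the {expected.value} view "
            f"but this trial is tagged {seq.view.value}"))
    return issues


def read_manifest(path: str | Path) -> dict[str, dict]:
    """Read a trial manifest (YAML or JSON).

    Maps trial_id -> {movement, view (optional), frames_path,
    calibration_trial_id (optional)}.
    """
    path = Path(path)
    text = path.read_text()
    if path.suffix in {".yaml", ".yml"}:
        data = yaml.safe_load(text)
    else:
        data = json.loads(text)
    if not isinstance(data, dict) or not data:
        raise ParseError(f"manifest {path} must map trial ids to trial records")
    return data


def load_trial(record: dict, base_dir: Path, person_index: int = 0,
               trial_id: str = "") -> PoseSequence:
    """Load one manifest entry into a PoseSequence."""
    frames_path = Path(record["frames_path"])
    if not frames_path.is_absolute():
        frames_path = base_dir / frames_path
    movement = Movement(record["movement"])
    view = View(record["view"]) if "view" in record else None
    return read_openpose_sequence(frames_path, movement, person_index,
                                  view=view, trial_id=trial_id)
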