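"""Confidence gating, Savitzky–Golay smoothing, and the torso reference.

Keypoint trajectories from a pose model are noisy and occasionally drop out.
The pipeline first gates samples whose confidence falls below a threshold and
fills them by linear interpolation along time, then smooths each coordinate
channel with a 5th-order Savitzky–Golay filter of window 13.  Gating runs
before smoothing because filtering across dropout zeros corrupts the
neighbouring frames.

The torso vector (neck KP1 → mid-hip KP8) is the body-fixed reference against
which arm angles are measured, so trunk lean does not contaminate the scores.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from .errors import ConfigurationError, MissingKeypointError
from .keypoints_io import (KEYPOINT_NAMES, MID_HIP, N_KEYPOINTS, NECK,
                           PoseFrame, PoseSequence)

logger = logging.getLogger(__name__)


@dataclass
class SmoothingConfig:
    """Savitzky–Golay smoothing and confidence-gating parameters.

    polyorder 5 / window 13 are the filter settings used throughout;
    min_confidence is the gating threshold below which a keypoint sample is
    treated as unreliable and interpolated.
    """

    polyorder: int = 5
    window: int = 13
    min_confidence: float = 0.1

    def __post_init__(self) -> None:
        if self.window % 2 == 0:
            raise ConfigurationError(f"window must be odd, got {self.window}")
        if self.window <= self.polyorder:
            raise ConfigurationError(
                f"window ({self.window}) must exceed polyorder ({self.polyorder})")
        if not 0.0 <= self.min_confidence <= 1.0:
            raise ConfigurationError(
                f"min_confidence must lie in [0, 1], got {self.min_confidence}")


def effective_window(n_frames: int, cfg: SmoothingConfig) -> int | None:
    """Largest usable odd window ≤ min(cfg.window, n_frames), > polyorder.

    Returns None when no valid window exists (sequence too short to smooth).
    """
    w = min(cfg.window, n_frames)
    if w % 2 == 0:
        w -= 1
    if w <= cfg.polyorder:
        return None
    return w


def gate_and_fill(seq: PoseSequence, cfg: SmoothingConfig | None = None) -> PoseSequence:
    """Mark low-confidence samples invalid and fill them by interpolation.

    Samples with confidence < min_confidence are replaced, per keypoint and
    coordinate, by linear interpolation between the nearest valid samples
    (nearest-value extension at the ends), with frame_index as the time axis
    so numbering gaps are respected.  Keypoints with no valid sample in any
    frame are left untouched and stay flagged invalid in the attached
    validity mask.  The operation is idempotent.
    """
    cfg = cfg or SmoothingConfig()
    arr = seq.as_array()
    t = seq.frame_indices().astype(float)
    valid = arr[:, :, 2] >= cfg.min_confidence
    # confidence 0 means missing regardless of threshold
    valid &= arr[:, :, 2] > 0.0
    coords = arr[:, :, :2].copy()
    for k in range(N_KEYPOINTS):
        vk = valid[:, k]
        if vk.all():
            continue
        if not vk.any():
            continue  # stays invalid; downstream raises if required
        for c in range(2):
            coords[~vk, k, c] = np.interp(t[~vk], t[vk], coords[vk, k, c])
    return seq.replace_frames(coords, validity=valid)


def smooth_sequence(seq: PoseSequence, cfg: SmoothingConfig | None = None) -> PoseSequence:
    """Savitzky–Golay filter each keypoint's x and y channel along time.

    Confidences (and the validity mask, if any) pass through untouched.  For
    sequences shorter than the configured window, the window shrinks to the
    largest valid odd value; if none exists, smoothing is skipped with a
    warning rather than failing on short clips.
    """
    cfg = cfg or SmoothingConfig()
    w = effective_window(seq.n_frames, cfg)
    if w is None:
        logger.warning(
            "sequence %s has %d frames; no odd window > polyorder %d fits, "
            "smoothing skipped", seq.trial_id, seq.n_frames, cfg.polyorder)
        return seq.replace_frames(seq.as_array()[:, :, :2])
    if w < cfg.window:
        logger.warning(
            "sequence %s has %d frames; smoothing window shrunk %d -> %d",
            seq.trial_id, seq.n_frames, cfg.window, w)
    coords = seq.as_array()[:, :, :2]
    smoothed = savgol_filter(coords, window_length=w, polyorder=cfg.polyorder,
                             axis=0, mode="interp")
    return seq.replace_frames(smoothed)


def preprocess(seq: PoseSequence, cfg: SmoothingConfig | None = None) -> PoseSequence:
    """gate_and_fill followed by smooth_sequence (the standard order)."""
    cfg = cfg or SmoothingConfig()
    return smooth_sequence(gate_and_fill(seq, cfg), cfg)


@dataclass
class TorsoVector:
    """Neck→mid-hip displacement in image pixels (y down)."""

    dx: float
    dy: float

    @property
    def magnitude(self) -> float:
        return math.hypot(self.dx, self.dy)

    def as_array(self) -> np.ndarray:
        return np.array([self.dx, self.dy])

    @property
    def angle_from_vertical_deg(self) -> float:
        """Signed lean of the torso from the image-vertical, degrees."""
        return math.degrees(math.atan2(self.dx, self.dy))


def torso_vector(frame: PoseFrame, validity: np.ndarray | None = None) -> TorsoVector:
    """Body position vector v_t from the neck (KP1) to the mid-hip (KP8)."""
    for idx in (NECK, MID_HIP):
        missing = (not validity[idx]) if validity is not None else frame.is_missing(idx)
        if missing:
            raise MissingKeypointError(
                f"cannot compute torso vector: {KEYPOINT_NAMES[idx]} (KP{idx}) "
                f"missing in frame {frame.frame_index}")
    d = frame.xy[MID_HIP] - frame.xy[NECK]
    return TorsoVector(float(d[0]), float(d[1]))
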