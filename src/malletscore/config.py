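"""Run-level configuration shared by the scorer and the CLI."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigurationError
from .preprocessing import SmoothingConfig


@dataclass
class RunConfig:
    """Everything tunable about a scoring run.

    symmetry_threshold_deg is the left/right angle difference (degrees) at or
    below which a trial whose better arm meets the top-grade condition is
    scored Grade V on both arms.  touch_limit is the hand-to-mouth touch
    threshold as a fraction of torso length.  hand_to_neck_coupling assigns
    both arms the lower of the two hand-to-neck grades (off by default).
    mirror flips the mediolateral sign convention for selfie-mode footage.
    """

    smoothing: SmoothingConfig = field(default_factory=SmoothingConfig)
    touch_limit: float = 0.35
    symmetry_threshold_deg: float = 15.0
    hand_to_neck_coupling: bool = False
    mirror: bool = False
    exclude_trials: list[str] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.symmetry_threshold_deg > 0:
            raise ConfigurationError("symmetry_threshold_deg must be > 0")
        if not 0 < self.touch_limit:
            raise ConfigurationError("touch_limit must be > 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        smoothing = SmoothingConfig(**data.pop("smoothing", {}))
        return cls(smoothing=smoothing, **data)
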