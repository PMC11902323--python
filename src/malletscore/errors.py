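"""Exception hierarchy for the malletscore pipeline."""


class MalletScoreError(Exception):
    """Base class for all malletscore errors."""


class ParseError(MalletScoreError):
    """A keypoint file could not be parsed; the message names the file."""


class EmptyInputError(MalletScoreError):
    """An operation received no usable data (no frames, no pairs, ...)."""


class ConfigurationError(MalletScoreError):
    """Invalid configuration (bad smoothing window, unknown criterion, ...)."""


class MissingKeypointError(MalletScoreError):
    """A keypoint required by an angle computation is missing in a frame."""


class DegenerateGeometryError(MalletScoreError):
    """Coincident keypoints produced a zero-magnitude segment vector."""


class CalibrationError(MalletScoreError):
    """Arm-length-ratio calibration failed or produced a non-positive length."""


class DomainError(MalletScoreError):
    """An angle lies outside the representable range of its criterion."""
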