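import numpy as np
import pytest

from malletscore.keypoints_io import Movement
from malletscore.scoring import score_trial
from malletscore.synthetic import BodyModel, constant_pose_trial


@pytest.fixture(scope="session")
def model() -> BodyModel:
    return BodyModel()


@pytest.fixture(scope="session")
def calibration(model):
    """Noise-free global-abduction trial for arm-length-ratio calibration."""
    return constant_pose_trial(Movement.GLOBAL_ABDUCTION, 90.0, model,
                               n_frames=15, trial_id="calib")


@pytest.fixture(scope="session")
def score_constant(model, calibration):
    """End-to-end grade of a held synthetic pose at a commanded angle."""

    def _score(movement: Movement, angle, n_frames: int = 15):
        movement = Movement(movement)
        seq = constant_pose_trial(movement, angle, model, n_frames=n_frames)
        calib = (calibration
                 if movement is Movement.GLOBAL_EXTERNAL_ROTATION else None)
        return score_trial(seq, calibration=calib)

    return _score


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
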