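import numpy as np
import pytest

try:
    from hypothesis import HealthCheck, settings

    settings.register_profile(
        "default",
        derandomize=True,
        max_examples=50,
        deadline=None,
        suppress_health_check=[HealthCheck.too_slow],
    )
    settings.load_profile("default")
except ImportError:  # pragma: no cover
    pass

from mirrorkit import make_calibration_script, sample_states
from mirrorkit.latency import PoseTrack, preprocess_track


@pytest.fixture(scope="session")
def calibration_script():
    return make_calibration_script()


@pytest.fixture(scope="session")
def calibration_yaw(calibration_script):
    """Noiseless 30 s calibration yaw track at 120 fps (3600 frames)."""
    samples = sample_states(calibration_script, fps=120, n_frames=3600)
    return np.array([s.state.pose.ry for s in samples])


@pytest.fixture(scope="session")
def calibration_track(calibration_yaw):
    """Preprocessed (z-transformed, smoothed) calibration reference track."""
    return preprocess_track(PoseTrack(fps=120, samples=calibration_yaw), smooth_window=5)
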