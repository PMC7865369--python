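import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import facepulse as fp

settings.register_profile(
    "default", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("default")


@pytest.fixture(scope="session")
def canonical_landmarks():
    """Template placed in a 512x512 frame."""
    return fp.generate_landmark_template(300.0, (256.0, 256.0), (512, 512))


@pytest.fixture(scope="session")
def small_video():
    """22 s synthetic recording at 256 px with the default facial profile.

    Long enough for breathing-rate estimation (>= 4 periods at 0.2 Hz) but
    cheap enough to share across the suite.
    """
    params = fp.default_params(duration_s=22.0, seed=11, noise_sd=0.5)
    frames, truth = fp.generate_video(params, frame_size=(256, 256))
    return frames, truth


@pytest.fixture(scope="session")
def small_analysis(small_video):
    frames, truth = small_video
    cfg = fp.AnalysisConfig(roi_size=10, top_n=50)
    return fp.analyze_recording(frames, truth.landmark_set, cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
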