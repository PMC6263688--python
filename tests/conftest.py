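import numpy as np
import pytest

from thermowelfare.config import preset
from thermowelfare.synthetic import BreathSceneConfig, OFTSceneConfig, make_breathing_video, make_oft_video


@pytest.fixture(scope="session")
def rat_config():
    return preset("rat")


@pytest.fixture(scope="session")
def breath_scene():
    """45-s rat-regime breathing scene at reduced geometry (160x120, 30 fps)."""
    cfg = BreathSceneConfig(
        frame_shape=(120, 160), fps=30.0, duration_s=45.0, rr_profile=54.0,
        noise_sigma_c=0.3, seed=11,
    )
    video, truth = make_breathing_video(cfg)
    return cfg, video, truth


@pytest.fixture(scope="session")
def oft_scene():
    """12-s Open Field scene with a moderately fast walk."""
    cfg = OFTSceneConfig(
        frame_shape=(240, 320), fps=30.0, duration_s=12.0, seed=3,
        speed_mean_px_s=60.0, noise_sigma_c=0.3,
    )
    video, truth = make_oft_video(cfg)
    return cfg, video, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
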