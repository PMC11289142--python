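import numpy as np
import pytest

from lasertrack import MotionParams, SceneConfig, TrackerParams, default_red_spec


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_scene():
    """Quarter-resolution scene (16 px/cm) with physical sizes unchanged."""
    return SceneConfig(
        image_width_px=160,
        image_height_px=160,
        body_axes_px=(30.0, 14.0),
        marker_radius_px=6.0,
        noise_sigma=0.0,
        n_frames=40,
        fps=20.0,
        seed=7,
    )


@pytest.fixture
def small_tracker():
    return TrackerParams(opening_radius_px=1, min_blob_px=5, max_jump_px=40.0)


@pytest.fixture
def red_spec():
    return default_red_spec()


@pytest.fixture
def motion():
    return MotionParams()
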