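import numpy as np
import pytest

from mirtrack.synthetic import MotionParams, SyntheticScene, render_image_stack, simulate_trajectory


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def single_spot_scene():
    """One bright stationary emitter rendered over 100 frames."""
    track = simulate_trajectory(
        MotionParams("stationary", n_frames=100), origin=(5.07, 4.93), track_id=0
    )
    scene = SyntheticScene(
        [track], seed=7, shape=(64, 64), photons_per_frame=5000.0, background=10.0
    )
    stack = render_image_stack(scene)
    return scene, stack
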