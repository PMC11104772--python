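import numpy as np
import pytest

from ciliaflow import CiliaSimParams, LayerMask, VideoStack, simulate_cilia_video


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_stack(rng):
    """64-frame random stack, 40x50 px, 1000 Hz."""
    frames = rng.uniform(0.1, 0.9, size=(64, 40, 50))
    return VideoStack(frames=frames, frame_rate_hz=1000.0, pixel_size_um=0.5)


@pytest.fixture
def full_mask():
    return LayerMask(mask=np.ones((40, 50), dtype=bool))


@pytest.fixture(scope="session")
def cilia_scene():
    """One clean 25 Hz beating video shared across tests.

    320 frames at 1000 Hz puts 25 Hz exactly on bin 8 (3.125 Hz spacing).
    """
    params = CiliaSimParams(frame_count=320, cbf_hz=25.0, noise_sigma=0.02, seed=11)
    stack, mask, truth = simulate_cilia_video(params)
    return stack, mask, truth
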