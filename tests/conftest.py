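import numpy as np
import pytest

from cartwheel.synthgen import DisplayParams, simulate_display_video


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def clean_scene():
    """Noise-free 3-male display video, 10 s at 30 fps."""
    params = DisplayParams(
        n_males=3, duration=10.0, fps=30.0, timing_noise_sd=0.0, height_noise_sd=0.0, seed=7
    )
    return simulate_display_video(params)
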