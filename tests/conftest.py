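import numpy as np
import pytest

from mealtrack.session_detector import SessionConfig
from mealtrack.synthetic_scene import render_background, render_sequence, scripted_meal

SCALE = 0.25  # all end-to-end tests run on a 160x120 grid


@pytest.fixture(scope="session")
def mini_scene():
    """One noise-free single-action meal scene shared across test modules."""
    script = scripted_meal(1, scale=SCALE, seed=7)
    frames, truth = render_sequence(script)
    background = render_background(script)
    return script, frames, truth, background


@pytest.fixture(scope="session")
def mini_cfg():
    return SessionConfig.scaled(SCALE)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
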