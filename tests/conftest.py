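import dataclasses

import numpy as np
import pytest
from hypothesis import settings

from thermobreath import SceneConfig, generate_scene

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")

#: Small, fast scene shared across test modules: 80×64 px, 6 s at 10 fps,
#: 30 bpm, noise-free.
SMALL = SceneConfig(
    frame_height=80,
    frame_width=64,
    fps=10.0,
    duration_s=6.0,
    rate_bpm=30.0,
    baseline_temp=33.0,
    amplitude=2.0,
    ambient_temp=20.0,
    noise_sd=0.0,
    nostril_radii=(6.0, 4.0),
    nostril_separation=24.0,
    motion_amplitude=2.0,
    seed=7,
)


@pytest.fixture(scope="session")
def small_config() -> SceneConfig:
    return SMALL


@pytest.fixture(scope="session")
def small_scene():
    return generate_scene(SMALL)


@pytest.fixture(scope="session")
def noisy_scene():
    return generate_scene(dataclasses.replace(SMALL, noise_sd=0.07))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
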