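import numpy as np
import pytest

from teadetect.data import SynthConfig, synth_scene


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_scene():
    """One 256-px synthetic scene with a handful of buds."""
    return synth_scene(SynthConfig(image_size=256, n_buds=(6, 10), seed=0))


@pytest.fixture(scope="session")
def scene_batch():
    """Eight seeded synthetic scenes (the smoke-training fixture)."""
    return [
        synth_scene(SynthConfig(image_size=256, n_buds=(6, 10), seed=s))
        for s in range(8)
    ]
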