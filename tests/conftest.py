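import numpy as np
import pytest

import vegsr


@pytest.fixture(scope="session")
def scene():
    """One deterministic default scene."""
    return vegsr.generate_scene(vegsr.SceneSpec(seed=42))


@pytest.fixture(scope="session")
def clean_scenes():
    """Ten clean scenes (no band misalignment) shared by oracle tests."""
    return vegsr.generate_samples(10, {"strong_noise_px": 0.0}, seed=7)


@pytest.fixture(scope="session")
def tiny_model():
    """A small SRCNet for shape/equivariance checks."""
    return vegsr.build_srcnet(vegsr.ModelConfig("srcnet", width=8, depth=2, growth=2))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
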