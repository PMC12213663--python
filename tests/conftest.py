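import numpy as np
import pytest

from cryoclem.synthetic import SceneSpec, generate_scene


@pytest.fixture(scope="session")
def noiseless_spec() -> SceneSpec:
    return SceneSpec(seed=42, noise_sigma=0.0, n_beads=12, n_gold50=10)


@pytest.fixture(scope="session")
def noiseless_manifest(noiseless_spec):
    return generate_scene(noiseless_spec)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
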