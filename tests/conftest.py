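import numpy as np
import pytest

from gliascore import generate_scene, random_scene_spec


@pytest.fixture(scope="session")
def demo_scene():
    """One mid-sized scene with known per-cell arm counts and decoy nuclei."""
    spec = random_scene_spec(
        (512, 512),
        8,
        seed=3,
        arm_counts=[2, 3, 4, 5, 6, 3, 4, 2],
        n_decoy_nuclei=3,
        n_astrocyte_filaments=4,
        n_neurite_tracts=5,
    )
    return generate_scene(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
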