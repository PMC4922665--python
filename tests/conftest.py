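import numpy as np
import pytest

from leafsen import SyntheticSceneSpec, asymmetric_edge_preset, generate_scene


@pytest.fixture(scope="session")
def green_scene():
    """Small non-senescent plant scene."""
    return generate_scene(
        SyntheticSceneSpec(image_size=(160, 160), leaf_count=5,
                           leaf_length=(45.0, 75.0), seed=101)
    )


@pytest.fixture(scope="session")
def senescent_scene():
    """Scene with a quarter of the plant senescent, bottom-weighted."""
    return generate_scene(
        SyntheticSceneSpec(image_size=(160, 160), leaf_count=5,
                           leaf_length=(45.0, 75.0),
                           senescent_fraction=0.25, seed=202)
    )


@pytest.fixture(scope="session")
def distortion_kernels():
    """Default strong distortion used across restoration tests."""
    return asymmetric_edge_preset(1.0, kernel_size=3, noise_sigma=0.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
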