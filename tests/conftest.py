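import numpy as np
import pytest

from plaqueseg import NetworkConfig, PhantomSpec, build_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_net_config():
    """A 32-pixel, width-4 model: same code path as the 512-scale network."""
    return NetworkConfig(input_size=32, base_width=4, depth=4,
                         cbam_reduction=2, seed=7)


@pytest.fixture
def small_spec():
    return PhantomSpec(image_size=64, noise_sigma=0.02)


@pytest.fixture(scope="session")
def small_dataset(tmp_path_factory):
    """40 images (20 originals) of 64x64 phantoms, shared across tests."""
    out = tmp_path_factory.mktemp("phantoms")
    rng = np.random.default_rng(99)
    spec = PhantomSpec(image_size=64, noise_sigma=0.02)
    return build_dataset(spec, n_originals=20, n_augmented=40,
                         out_dir=out, rng=rng)
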