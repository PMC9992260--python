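import numpy as np
import pytest

from dircn import make_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_complex(rng, shape):
    return rng.standard_normal(shape) + 1j * rng.standard_normal(shape)


@pytest.fixture(scope="session")
def small_dataset(tmp_path_factory):
    """Two tiny synthetic volumes (32×32, 2 coils) on disk."""
    path = tmp_path_factory.mktemp("data")
    make_dataset(path, n_volumes=2, slices_per_volume=2, seed=7,
                 size=32, n_coils=2, noise_sigma=0.005)
    return path
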