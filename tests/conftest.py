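import numpy as np
import pytest

from medsegmesh.phantom_eval import PhantomSpec, make_disk_phantom, make_tissue_phantom


@pytest.fixture(scope="session")
def disk_clean():
    """Noise-free 128x128 disk phantom (fg 200, bg 50, r 30)."""
    return make_disk_phantom(shape=(128, 128), radius=30, fg=200, bg=50)


@pytest.fixture(scope="session")
def disk_noisy():
    return make_disk_phantom(shape=(128, 128), radius=30, fg=200, bg=50, noise_percent=3, seed=1)


@pytest.fixture(scope="session")
def tissue_3pct():
    """Three-class tissue phantom, 3% noise, no bias, seed 1."""
    return make_tissue_phantom(PhantomSpec(noise_percent=3, seed=1))


@pytest.fixture(scope="session")
def tissue_bias():
    """Three-class tissue phantom, 3% noise + 40% bias field, seed 1."""
    return make_tissue_phantom(PhantomSpec(noise_percent=3, bias_percent=40, seed=1))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
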