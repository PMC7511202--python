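import numpy as np
import pytest

from ipnet.data import BlobTaskSpec, make_blob_task

DEEP_ARCH = [20] + [32] * 7 + [10]  # nine layers in total


@pytest.fixture(scope="session")
def blob_task():
    """The reference 10-class, 20-dimensional uncentered blob task."""
    return make_blob_task(BlobTaskSpec(seed=0))


@pytest.fixture(scope="session")
def tiny_task():
    """A small 3-class task for fast training tests."""
    return make_blob_task(
        BlobTaskSpec(n_classes=3, dims=5, n_per_class=60, noise_sigma=0.5, seed=1)
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
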