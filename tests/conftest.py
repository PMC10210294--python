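import numpy as np
import pytest

from etgpda import HyperParams, benchmark_world


@pytest.fixture(scope="session")
def small_world():
    return benchmark_world("small", seed=7)


@pytest.fixture()
def fast_hp():
    """Few-epoch hyper-parameters for tests that exercise training."""
    return HyperParams(epochs=30, seed=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
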