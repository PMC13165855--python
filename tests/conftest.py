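import numpy as np
import pytest

from dcamnet.model import DCAMNetConfig


@pytest.fixture
def tiny_config():
    """A network configuration small enough for brute-force oracles."""
    return DCAMNetConfig(
        C=3, T=50, n_bands=4, K=2, N=4, L=5, r=2, m=4, w=10, h=2, dropout=0.0
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
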