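import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def constant_stack():
    """35 identical noise-free 16x12 frames."""
    frame = np.full((12, 16), 80, dtype=np.uint8)
    return np.repeat(frame[None], 35, axis=0)
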