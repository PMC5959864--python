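import numpy as np
import pytest

from withervision.features import LeafImage


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_leaf_image(seed: int, size=(64, 64), bit_depth=8) -> LeafImage:
    rng = np.random.default_rng(seed)
    max_val = 2**bit_depth - 1
    px = rng.integers(0, max_val + 1, size=(*size, 3))
    dtype = np.uint16 if bit_depth == 16 else np.uint8
    return LeafImage(pixels=px.astype(dtype), bit_depth=bit_depth)


def constant_image(value, size=(16, 16), bit_depth=8) -> LeafImage:
    px = np.full((*size, 3), 0, dtype=np.uint16 if bit_depth == 16 else np.uint8)
    px[..., 0], px[..., 1], px[..., 2] = value
    return LeafImage(pixels=px, bit_depth=bit_depth)
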