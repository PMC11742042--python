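from __future__ import annotations

import numpy as np
import pytest

from neuritequant import ImageField


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def make_field(pixels, pixel_size=0.65, bit_depth=16, channel="calcein") -> ImageField:
    return ImageField(
        pixels=np.asarray(pixels),
        pixel_size=pixel_size,
        bit_depth=bit_depth,
        channel=channel,
    )


@pytest.fixture
def field_factory():
    return make_field
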