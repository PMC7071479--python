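import numpy as np
import pytest

from fdlquant.image_io import TwoChannelImage


@pytest.fixture
def make_image():
    """Build a TwoChannelImage from any array-likes (cast to uint8)."""

    def _make(red, green) -> TwoChannelImage:
        return TwoChannelImage(
            red=np.asarray(red, dtype=np.uint8),
            green=np.asarray(green, dtype=np.uint8),
        )

    return _make


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
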