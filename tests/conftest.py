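import numpy as np
import pytest

from ihcquant.config import default_config


@pytest.fixture(scope="session")
def cfg():
    return default_config()


@pytest.fixture()
def rng():
    return np.random.default_rng(2026)


def random_image(rng, h=8, w=8):
    return rng.integers(0, 256, size=(h, w, 3), dtype=np.uint8)


def random_color_range(rng):
    from ihcquant.color import ColorRange

    bounds = []
    for _ in range(3):
        lo, hi = sorted(int(v) for v in rng.integers(0, 256, size=2))
        bounds += [lo, hi]
    return ColorRange(*bounds)
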