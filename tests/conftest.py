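import sys
from pathlib import Path

import numpy as np
import pytest
from hypothesis import settings

# make the sibling oracles module importable regardless of rootdir
sys.path.insert(0, str(Path(__file__).parent))

settings.register_profile("repro", settings(derandomize=True, deadline=None))
settings.load_profile("repro")


@pytest.fixture
def rng():
    return np.random.default_rng(20210310)


def random_binary_images(n, max_side=64, seed=0):
    """Random binary images with varied density, side length 1..max_side."""
    gen = np.random.default_rng(seed)
    for _ in range(n):
        h = int(gen.integers(1, max_side + 1))
        w = int(gen.integers(1, max_side + 1))
        density = float(gen.uniform(0.05, 0.95))
        yield gen.random((h, w)) < density


def random_gray_images(n, side=48, seed=0):
    """Random smooth-ish uint8 grayscale images (blurred noise)."""
    from scipy import ndimage

    gen = np.random.default_rng(seed)
    for _ in range(n):
        base = gen.random((side, side))
        smooth = ndimage.uniform_filter(base, size=int(gen.integers(1, 6)))
        lo, hi = smooth.min(), smooth.max()
        scaled = (smooth - lo) / (hi - lo) if hi > lo else smooth * 0
        yield (scaled * 255).astype(np.uint8)
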