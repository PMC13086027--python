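import numpy as np
import pytest

from collateralfd.preprocess import GANGLIONIC, SUPRAGANGLIONIC
from collateralfd.synth import FractalFixtureSpec, VascularTreeSpec, make_fractal, make_vascular_slice


def brute_force_box_count(mask: np.ndarray, s: int, dy: int = 0, dx: int = 0) -> int:
    """Naive per-box scan: the independent oracle for grid box counting.

    The grid origin sits at (-dy, -dx); border-partial boxes count.
    """
    h, w = mask.shape
    count = 0
    r = -dy
    while r < h:
        c = -dx
        while c < w:
            block = mask[max(r, 0) : min(r + s, h), max(c, 0) : min(c + s, w)]
            if block.size and block.any():
                count += 1
            c += s
        r += s
    return count


@pytest.fixture(scope="session")
def sierpinski7():
    spec = FractalFixtureSpec("sierpinski_triangle", depth=7)
    return make_fractal(spec), spec.theoretical_dimension


@pytest.fixture(scope="session")
def filled_square64():
    return make_fractal(FractalFixtureSpec("filled_square", size=64))


def phantom_slices(seed: int, depth_sym: int = 6, depth_contra: int = 6, noise: float = 0.0):
    """Two-level phantom case: independent tree geometry per level."""
    slices = {}
    for level, offset in ((GANGLIONIC, 0), (SUPRAGANGLIONIC, 100000)):
        spec = VascularTreeSpec(
            depth_symptomatic=depth_sym,
            depth_contralateral=depth_contra,
            noise_sigma=noise,
            seed=seed + offset,
            level=level,
        )
        cta, _ = make_vascular_slice(spec)
        slices[level] = cta
    return slices
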