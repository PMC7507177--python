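import numpy as np
import pytest

from vascnet import PhantomSpec, generate_phantom


def make_bar(shape, row_center, width, col_start, col_stop):
    """Axis-aligned horizontal bar mask of odd width centered on a row."""
    mask = np.zeros(shape, dtype=bool)
    half = width // 2
    mask[row_center - half : row_center + half + 1, col_start:col_stop] = True
    return mask


@pytest.fixture(scope="session")
def small_tree_phantom():
    """One modest noise-free random-tree phantom for reuse across tests."""
    spec = PhantomSpec(image_shape=(320, 320), n_branches=4, seed=11)
    truth, img = generate_phantom(spec)
    return spec, truth, img


@pytest.fixture(scope="session")
def random_masks_16():
    """120 random masks up to 16×16 with varied densities (fixed seed)."""
    rng = np.random.default_rng(1234)
    masks = []
    for _ in range(120):
        h = int(rng.integers(3, 17))
        w = int(rng.integers(3, 17))
        p = float(rng.uniform(0.15, 0.85))
        masks.append(rng.random((h, w)) < p)
    return masks
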