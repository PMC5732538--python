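import numpy as np
import pytest

from sipkit.preprocess import RasterImage


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def noise_rgb(rng):
    """Small random RGB image."""
    return RasterImage(rng.uniform(0, 1, (60, 80, 3)), "RGB")


@pytest.fixture
def noise_gray(rng):
    return RasterImage(rng.uniform(0, 1, (64, 64)), "GRAY")


def make_edges(rows, cols, orientations, strengths, h=400, w=300):
    """Hand-built EdgeResponseSet for histogram/pairwise tests."""
    from sipkit.edge_entropy import EdgeResponseSet

    return EdgeResponseSet(
        rows=np.asarray(rows, dtype=np.int64),
        cols=np.asarray(cols, dtype=np.int64),
        orientations=np.asarray(orientations, dtype=np.int64),
        strengths=np.asarray(strengths, dtype=np.float64),
        image_height=h,
        image_width=w,
    )
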