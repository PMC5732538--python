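"""Box-counting fractal dimension of the Canny-binarized image.

The image is edge-filtered (Canny), empty borders are cropped, and the
remaining binary pattern is covered by meshes of decreasing box size eps
(powers of 2 from half the shorter side down to 2 px, anchored at the
top-left corner).  The dimension D is the OLS slope of log N(eps) versus
log(1/eps), where N counts boxes containing at least one set pixel; D runs
from ~1 for simple line patterns to ~2 for space-filling ones.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.feature import canny

from .preprocess import DegenerateImageError, RasterImage, crop_empty_border, to_gray_luma

__all__ = ["BoxCountSeries", "binarize_canny", "box_count", "fit_dimension", "fractal_dimension"]

CANNY_SIGMA = 1.0
CANNY_LOW = 0.1
CANNY_HIGH = 0.2
MIN_BOX = 2


@dataclass(frozen=True)
class BoxCountSeries:
    box_sizes: np.ndarray  # strictly decreasing eps, px
    counts: np.ndarray  # N(eps), positive integers


def binarize_canny(img: RasterImage) -> np.ndarray:
    """Canny edge map (uint8 0/1) of the luma-grayscale image.

    Gaussian sigma 1.0, hysteresis thresholds 0.1/0.2 on the [0, 1]
    intensity scale; fixed so that runs are reproducible.
    """
    gray = to_gray_luma(img)
    edges = canny(gray.pixels, sigma=CANNY_SIGMA, low_threshold=CANNY_LOW, high_threshold=CANNY_HIGH)
    return edges.astype(np.uint8)


def box_count(binary: np.ndarray) -> BoxCountSeries:
    """Count occupied mesh boxes for a schedule of decreasing box sizes.

    The input is cropped to its bounding box first; the mesh is anchored at
    the top-left corner, and partial boxes at the right/bottom count like
    full ones.
    """
    binary = crop_empty_border(np.asarray(binary) != 0)
    h, w = binary.shape

    def schedule(limit: int) -> list[int]:
        sizes, eps = [], MIN_BOX
        while eps <= limit:
            sizes.append(eps)
            eps *= 2
        return sizes

    # base the schedule on the shorter cropped side; thin patterns (e.g. a
    # 1-px line) would leave fewer than 3 sizes, so fall back to the longer
    sizes = schedule(min(h, w) // 2)
    if len(sizes) < 3:
        sizes = schedule(max(h, w) // 2)
    if not sizes:
        sizes = [MIN_BOX]
    sizes = sizes[::-1]  # strictly decreasing
    counts = []
    for eps in sizes:
        ph = (-h) % eps
        pw = (-w) % eps
        padded = np.pad(binary, ((0, ph), (0, pw)))
        blocks = padded.reshape(padded.shape[0] // eps, eps, padded.shape[1] // eps, eps)
        counts.append(int(blocks.any(axis=(1, 3)).sum()))
    return BoxCountSeries(np.array(sizes, dtype=float), np.array(counts, dtype=float))


def fit_dimension(series: BoxCountSeries) -> float:
    """OLS slope of log N(eps) vs log(1/eps)."""
    if series.box_sizes.size < 3:
        raise ValueError(f"need >= 3 box sizes for a dimension fit, got {series.box_sizes.size}")
    x = np.log(1.0 / series.box_sizes)
    y = np.log(series.counts)
    slope = np.polyfit(x, y, 1)[0]
    return float(slope)


def fractal_dimension(img: RasterImage) -> float:
    """End-to-end box-counting dimension of an image (NaN if degenerate)."""
    edges = binarize_canny(img)
    try:
        series = box_count(edges)
        return fit_dimension(series)
    except (DegenerateImageError, ValueError):
        return float("nan")
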