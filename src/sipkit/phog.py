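"""Self-similarity from a pyramid of histograms of oriented gradients (PHOG).

The image is converted to CIE Lab and rescaled to 100,000 pixels.  Luminance
gradients are computed per channel by central differences; each pixel
contributes the orientation (16 bins over the full 360°, so gradient polarity
is kept) of the channel with the largest gradient magnitude, weighted by that
magnitude.  Histograms are computed on a 4-way nested partition of the image
(level 0 = whole image ... level 3 = 64 sections) and each section histogram
is compared to the ground (level-0) histogram with the histogram intersection
kernel on L1-normalized histograms.  Self-similarity is the mean intersection
over levels 1-3; values near 1 mean the parts resemble the whole.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocess import DegenerateImageError, RasterImage, resize_to_pixel_count, to_lab

__all__ = [
    "SectionHistogram",
    "compute_hog",
    "build_pyramid",
    "histogram_intersection",
    "self_similarity",
]

N_BINS = 16
ANALYSIS_PIXELS = 100_000
LEVELS = (1, 2, 3)


@dataclass(frozen=True)
class SectionHistogram:
    level: int  # 0..3
    section_index: int  # 0 .. 4**level - 1
    bins: np.ndarray  # 16 non-negative weights, unnormalized


def _gradient_field(lab: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel winning-channel gradient magnitude and 16-bin orientation index.

    Central differences with replicate borders per Lab channel; the pixel's
    contributing channel is the one with maximal gradient magnitude.
    """
    g_row = np.empty_like(lab)
    g_col = np.empty_like(lab)
    for c in range(3):
        g_row[..., c], g_col[..., c] = np.gradient(lab[..., c])
    mag = np.hypot(g_row, g_col)
    win = np.argmax(mag, axis=2)
    rr, cc = np.indices(win.shape)
    gr = g_row[rr, cc, win]
    gc = g_col[rr, cc, win]
    m = mag[rr, cc, win]
    ang = np.mod(np.degrees(np.arctan2(gr, gc)), 360.0)
    idx = np.minimum((ang / (360.0 / N_BINS)).astype(np.int64), N_BINS - 1)
    return m, idx


def compute_hog(magnitude: np.ndarray, bin_index: np.ndarray, region: tuple[int, int, int, int]) -> np.ndarray:
    """Unnormalized 16-bin HOG over ``region`` = (row0, row1, col0, col1)."""
    r0, r1, c0, c1 = region
    if r1 <= r0 or c1 <= c0:
        raise ValueError(f"empty region {region}")
    m = magnitude[r0:r1, c0:c1].ravel()
    b = bin_index[r0:r1, c0:c1].ravel()
    return np.bincount(b, weights=m, minlength=N_BINS)


def _sections(h: int, w: int, level: int):
    """Section rectangles of the 4**level partition, row-major.

    Dimensions that do not divide evenly give the extra pixels to the
    bottom/right sections (np.array_split semantics reversed).
    """
    n = 2**level
    row_edges = [i * h // n for i in range(n + 1)]
    col_edges = [i * w // n for i in range(n + 1)]
    for i in range(n):
        for j in range(n):
            yield (row_edges[i], row_edges[i + 1], col_edges[j], col_edges[j + 1])


def build_pyramid(img: RasterImage) -> list[SectionHistogram]:
    """All 85 section histograms (1 + 4 + 16 + 64) of the PHOG pyramid.

    The input may be any RasterImage; conversion to Lab and resizing to the
    analysis size happen internally.
    """
    lab = to_lab(resize_to_pixel_count(img, ANALYSIS_PIXELS))
    h, w = lab.height, lab.width
    if h < 8 or w < 8:
        raise DegenerateImageError(f"image {h}x{w} too small for a level-3 pyramid")
    mag, idx = _gradient_field(lab.pixels)
    out = []
    for level in range(4):
        for si, region in enumerate(_sections(h, w, level)):
            out.append(SectionHistogram(level, si, compute_hog(mag, idx, region)))
    return out


def histogram_intersection(h1: np.ndarray, h2: np.ndarray) -> float:
    """Histogram intersection kernel: sum of bin-wise minima.

    Both inputs must be L1-normalized; 1 for identical histograms, 0 for
    disjoint supports.
    """
    h1 = np.asarray(h1, dtype=np.float64)
    h2 = np.asarray(h2, dtype=np.float64)
    for h in (h1, h2):
        if not np.isclose(h.sum(), 1.0, atol=1e-8):
            raise ValueError("histogram_intersection expects L1-normalized histograms")
    return float(np.minimum(h1, h2).sum())


def self_similarity(img: RasterImage) -> float:
    """Mean histogram intersection of section vs ground histograms, levels 1-3.

    Sections with all-zero histograms are excluded; the result lies in
    [0, 1].  NaN for a fully constant image (no gradients anywhere).
    """
    pyramid = build_pyramid(img)
    ground = pyramid[0].bins
    if ground.sum() == 0:
        return float("nan")
    g = ground / ground.sum()
    level_means = []
    for level in LEVELS:
        vals = [
            histogram_intersection(sh.bins / sh.bins.sum(), g)
            for sh in pyramid
            if sh.level == level and sh.bins.sum() > 0
        ]
        if vals:
            level_means.append(float(np.mean(vals)))
    if not level_means:
        return float("nan")
    return float(np.mean(level_means))
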