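"""First- and second-order Shannon entropy of edge orientations.

Edges are extracted with a bank of 24 odd-symmetric (edge-sensitive) Gabor
filters spanning a full rotation in 15° steps.  First-order entropy measures
how evenly edge orientations are distributed over the whole image;
second-order entropy measures how statistically independent the orientations
of edge pairs are as a function of their distance ``d`` and relative
direction ``alpha``.

Analysis happens at a fixed size of 120,000 total pixels; the 10,000
strongest per-pixel winning responses are kept, excluding a 15-pixel border.
Undefined results (degenerate images) are returned as NaN.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import fftconvolve

from .preprocess import DegenerateImageError, RasterImage, resize_to_pixel_count, to_gray_luma

__all__ = [
    "EdgeResponseSet",
    "ThetaHistogramGrid",
    "build_gabor_bank",
    "extract_edges",
    "first_order_entropy",
    "orientation_histogram",
    "accumulate_pairs",
    "second_order_entropy",
]

N_ORIENTATIONS = 24
MAX_RESPONSES = 10_000
BORDER_PX = 15
ANALYSIS_PIXELS = 120_000
N_DISTANCE_BINS = 500
N_DIRECTION_BINS = 48
#: distance bins (inclusive) averaged into the scalar second-order entropy
D_AVERAGE_RANGE = (20, 80)

GABOR_WAVELENGTH = 8.0  # px at analysis size
GABOR_SIGMA = 0.56 * GABOR_WAVELENGTH
GABOR_TRUNCATE = 3.0  # kernel cut at this many sigma


@dataclass(frozen=True)
class EdgeResponseSet:
    """Positions, orientation indices and strengths of retained edge responses."""

    rows: np.ndarray  # int, 0-based
    cols: np.ndarray
    orientations: np.ndarray  # int in [0, 24)
    strengths: np.ndarray  # > 0, descending
    image_height: int
    image_width: int

    def __len__(self) -> int:
        return int(self.rows.size)


@dataclass(frozen=True)
class ThetaHistogramGrid:
    """Pairwise accumulation grid: 500 distance x 48 direction x 24 theta bins."""

    weights: np.ndarray  # (500, 48, 24), non-negative
    distance_bin_width: float = 1.0

    def __post_init__(self) -> None:
        if self.weights.shape != (N_DISTANCE_BINS, N_DIRECTION_BINS, N_ORIENTATIONS):
            raise ValueError(f"grid must be {(N_DISTANCE_BINS, N_DIRECTION_BINS, N_ORIENTATIONS)}, got {self.weights.shape}")


def build_gabor_bank(n_orientations: int = N_ORIENTATIONS) -> list[np.ndarray]:
    """Odd-symmetric Gabor kernels at angles ``k * 360/n``, k = 0..n-1.

    Sine-phase (zero-mean) kernels respond to step edges, not to lines or
    constant regions.  The kernel at angle 180° is the negation of the kernel
    at 0°, so the two halves of the bank encode edge polarity.
    """
    if n_orientations < 2 or n_orientations % 2 != 0:
        raise ValueError(f"n_orientations must be even and >= 2, got {n_orientations}")
    half = int(np.ceil(GABOR_TRUNCATE * GABOR_SIGMA))
    rr, cc = np.mgrid[-half : half + 1, -half : half + 1].astype(np.float64)
    kernels = []
    for k in range(n_orientations):
        theta = np.deg2rad(k * 360.0 / n_orientations)
        # x' along the filter's modulation axis; (row, col) with y = -row
        # so that angles run counter-clockwise from east.
        xp = cc * np.cos(theta) + (-rr) * np.sin(theta)
        yp = -cc * np.sin(theta) + (-rr) * np.cos(theta)
        env = np.exp(-(xp**2 + yp**2) / (2.0 * GABOR_SIGMA**2))
        kern = env * np.sin(2.0 * np.pi * xp / GABOR_WAVELENGTH)
        kern -= kern.mean()  # enforce exact zero mean despite truncation
        kernels.append(kern)
    return kernels


def extract_edges(img: RasterImage) -> EdgeResponseSet:
    """Extract the strongest oriented edge responses of an image.

    The image is converted to luma grayscale and rescaled to 120,000 total
    pixels.  Each interior pixel (>= 15 px from every border) is assigned the
    orientation of its maximal rectified Gabor response; the 10,000 globally
    strongest winners are retained (fewer if fewer positive responses exist).
    Ties at the cutoff are broken by (row, col, orientation) order.
    """
    gray = resize_to_pixel_count(to_gray_luma(img), ANALYSIS_PIXELS)
    h, w = gray.height, gray.width
    if h <= 2 * BORDER_PX or w <= 2 * BORDER_PX:
        raise DegenerateImageError(f"image {h}x{w} has no interior beyond the {BORDER_PX}-px border")

    # The bank is antisymmetric: response at k+12 is the negation of the
    # response at k, so 12 convolutions cover all 24 rectified channels.
    kernels = build_gabor_bank(N_ORIENTATIONS)
    resp = np.stack(
        [fftconvolve(gray.pixels, kern, mode="same") for kern in kernels[: N_ORIENTATIONS // 2]]
    )  # (12, h, w)
    best12 = np.argmax(np.abs(resp), axis=0)
    rr, cc = np.indices((h, w))
    signed = resp[best12, rr, cc]
    strength = np.abs(signed)
    orient = np.where(signed >= 0, best12, best12 + N_ORIENTATIONS // 2)

    interior = np.zeros((h, w), dtype=bool)
    interior[BORDER_PX : h - BORDER_PX, BORDER_PX : w - BORDER_PX] = True
    # FFT round-off leaves ~1e-15 responses on constant regions; a small
    # absolute floor keeps only genuine edge responses
    keep = interior & (strength > 1e-9)
    rows, cols = np.nonzero(keep)
    s = strength[rows, cols]
    k = orient[rows, cols]
    order = np.lexsort((k, cols, rows, -s))[:MAX_RESPONSES]
    return EdgeResponseSet(
        rows=rows[order], cols=cols[order], orientations=k[order],
        strengths=s[order], image_height=h, image_width=w,
    )


def orientation_histogram(edges: EdgeResponseSet) -> np.ndarray:
    """Strength-weighted 24-bin orientation histogram (unnormalized)."""
    return np.bincount(edges.orientations, weights=edges.strengths, minlength=N_ORIENTATIONS)


def _entropy_bits(p: np.ndarray) -> float:
    """Shannon entropy in bits of a probability vector (0 log 0 := 0)."""
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def first_order_entropy(edges: EdgeResponseSet) -> float:
    """Entropy in bits of the normalized strength-weighted orientation histogram.

    Maximal (log2 24 ≈ 4.585) when all 24 orientations carry equal strength;
    NaN for an empty edge set.
    """
    if len(edges) == 0:
        return float("nan")
    hist = orientation_histogram(edges)
    return _entropy_bits(hist / hist.sum())


def accumulate_pairs(edges: EdgeResponseSet, block: int = 256) -> ThetaHistogramGrid:
    """Accumulate all ordered edge pairs into the (d, alpha, theta) grid.

    For each ordered pair (i, j) the frame is rotated so that the reference
    edge i is horizontal: alpha is the direction of the displacement vector
    from i to j in that rotated frame (48 bins of 7.5°), d the Euclidean
    distance (500 bins of 1 px; pairs at d = 0 or d >= 500 are skipped), and
    theta the relative orientation (j - i, 24 bins).  Each pair contributes
    the product of the two strengths.  Evaluation is chunked over reference
    edges; the result is independent of the chunking.
    """
    n = len(edges)
    if n < 2:
        raise DegenerateImageError("pairwise accumulation needs at least 2 edges")
    rows = edges.rows.astype(np.float64)
    cols = edges.cols.astype(np.float64)
    k = edges.orientations.astype(np.int64)
    s = edges.strengths.astype(np.float64)
    bin_deg = 360.0 / N_DIRECTION_BINS

    flat = np.zeros(N_DISTANCE_BINS * N_DIRECTION_BINS * N_ORIENTATIONS)
    for lo in range(0, n, block):
        hi = min(lo + block, n)
        dr = rows[None, :] - rows[lo:hi, None]  # (b, n)
        dc = cols[None, :] - cols[lo:hi, None]
        dist = np.hypot(dr, dc)
        mask = (dist > 0) & (dist < N_DISTANCE_BINS)
        bi, bj = np.nonzero(mask)
        if bi.size == 0:
            continue
        dbin = dist[bi, bj].astype(np.int64)
        # displacement direction, CCW from east (y = -row), in the frame
        # rotated so the reference edge orientation is 0°
        phi = np.degrees(np.arctan2(-dr[bi, bj], dc[bi, bj]))
        ki = k[lo + bi]
        alpha = np.mod(phi - ki * (360.0 / N_ORIENTATIONS), 360.0)
        abin = np.minimum((alpha / bin_deg).astype(np.int64), N_DIRECTION_BINS - 1)
        tbin = np.mod(k[bj] - ki, N_ORIENTATIONS)
        w = s[lo + bi] * s[bj]
        idx = (dbin * N_DIRECTION_BINS + abin) * N_ORIENTATIONS + tbin
        flat += np.bincount(idx, weights=w, minlength=flat.size)
    return ThetaHistogramGrid(flat.reshape(N_DISTANCE_BINS, N_DIRECTION_BINS, N_ORIENTATIONS))


def second_order_entropy(grid: ThetaHistogramGrid, d_range: tuple[int, int] = D_AVERAGE_RANGE) -> float:
    """Mean entropy in bits of the theta histograms over d bins 20-80.

    Per (d, alpha) cell the 24-bin theta histogram is normalized and its
    Shannon entropy computed; cell entropies are averaged over the 48
    directions per distance (empty cells excluded), then over the distance
    range.  NaN when every cell in the range is empty.
    """
    w = grid.weights[d_range[0] : d_range[1] + 1]  # (D, 48, 24)
    totals = w.sum(axis=2)  # (D, 48)
    populated = totals > 0
    if not populated.any():
        return float("nan")
    with np.errstate(divide="ignore", invalid="ignore"):
        p = w / totals[..., None]
        cell_h = -np.nansum(np.where(p > 0, p * np.log2(p), 0.0), axis=2)
    per_d_sum = np.where(populated, cell_h, 0.0).sum(axis=1)
    n_cells = populated.sum(axis=1)
    has_d = n_cells > 0
    per_d = per_d_sum[has_d] / n_cells[has_d]
    return float(per_d.mean())
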