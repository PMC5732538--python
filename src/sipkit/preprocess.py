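"""Image loading and the preprocessing transforms shared by the SIP stages.

All pixel data is held as float64 in [0, 1] (integer inputs are divided by
their maximum code value).  Coordinates are 0-based ``(row, column)`` with the
row axis increasing downward; every module in the package shares this
convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image, UnidentifiedImageError
from skimage.color import rgb2lab
from skimage.transform import resize

__all__ = [
    "RasterImage",
    "load_image",
    "to_gray_luma",
    "to_lab",
    "resize_to_pixel_count",
    "pad_to_square_mean_gray",
    "crop_empty_border",
    "DegenerateImageError",
]

#: ITU-R 601-2 luma weights for R, G, B.
LUMA_WEIGHTS = (0.299, 0.587, 0.114)


class DegenerateImageError(ValueError):
    """Raised when an image carries no usable structure for an operation."""


@dataclass(frozen=True)
class RasterImage:
    """A pixel grid with a colorspace tag.

    ``pixels`` is ``(H, W)`` for GRAY and ``(H, W, 3)`` for RGB/LAB.  GRAY and
    RGB intensities live in [0, 1]; LAB carries L in [0, 100] and signed a/b.
    """

    pixels: np.ndarray
    colorspace: str  # one of {"GRAY", "RGB", "LAB"}

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        object.__setattr__(self, "pixels", px)
        if self.colorspace not in ("GRAY", "RGB", "LAB"):
            raise ValueError(f"unknown colorspace {self.colorspace!r}")
        if self.colorspace == "GRAY":
            if px.ndim != 2:
                raise ValueError("GRAY image must be 2-D")
        else:
            if px.ndim != 3 or px.shape[2] != 3:
                raise ValueError(f"{self.colorspace} image must have 3 planes")
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError("image must be at least 1x1")

    @property
    def height(self) -> int:
        return int(self.pixels.shape[0])

    @property
    def width(self) -> int:
        return int(self.pixels.shape[1])


def load_image(path: str | Path) -> RasterImage:
    """Load a PNG/JPEG/TIFF file as a GRAY or RGB :class:`RasterImage`.

    Intensities are rescaled to [0, 1] by the input's maximum code value
    (255 for 8-bit, 65535 for 16-bit).  Palette and alpha images are
    converted to RGB; single-band images stay GRAY.
    """
    path = Path(path)
    try:
        with Image.open(path) as im:
            im.load()
            if im.mode in ("1", "L", "I;16", "I"):
                scale = {"1": 1.0, "L": 255.0, "I;16": 65535.0, "I": 65535.0}[im.mode]
                arr = np.asarray(im, dtype=np.float64) / scale
                return RasterImage(np.clip(arr, 0.0, 1.0), "GRAY")
            if im.mode == "F":
                raise ValueError(f"unsupported bit depth / mode 'F' in {path}")
            im = im.convert("RGB")
            arr = np.asarray(im, dtype=np.float64) / 255.0
            return RasterImage(arr, "RGB")
    except (UnidentifiedImageError, OSError) as exc:
        raise IOError(f"cannot read image file {path}: {exc}") from exc


def to_gray_luma(img: RasterImage) -> RasterImage:
    """ITU-R 601-2 luma conversion: gray = 0.299 R + 0.587 G + 0.114 B.

    GRAY input is returned unchanged; LAB input is rejected.
    """
    if img.colorspace == "GRAY":
        return img
    if img.colorspace == "LAB":
        raise ValueError("to_gray_luma expects RGB or GRAY input, got LAB")
    r, g, b = LUMA_WEIGHTS
    gray = r * img.pixels[..., 0] + g * img.pixels[..., 1] + b * img.pixels[..., 2]
    return RasterImage(gray, "GRAY")


def to_lab(img: RasterImage) -> RasterImage:
    """Convert to CIE L*a*b* (sRGB input, D65 white point).

    GRAY input is replicated to three channels before conversion, so a
    grayscale image maps onto the neutral (a = b = 0) axis.
    """
    if img.colorspace == "LAB":
        return img
    rgb = img.pixels
    if img.colorspace == "GRAY":
        rgb = np.stack([rgb, rgb, rgb], axis=-1)
    return RasterImage(rgb2lab(rgb), "LAB")


def resize_to_pixel_count(img: RasterImage, target: int) -> RasterImage:
    """Isotropically rescale so that width*height is within 1% of ``target``.

    Bicubic interpolation; the aspect ratio is preserved.  An image already
    at the target area is returned unchanged.  Upscaling is permitted.
    """
    if target < 1:
        raise ValueError(f"target pixel count must be >= 1, got {target}")
    h, w = img.height, img.width
    if abs(h * w - target) <= 0.01 * target:
        return img
    s = np.sqrt(target / (h * w))
    new_h = max(1, round(h * s))
    new_w = max(1, round(w * s))
    if (new_h, new_w) == (h, w):
        return img
    shape = (new_h, new_w) if img.colorspace == "GRAY" else (new_h, new_w, 3)
    out = resize(img.pixels, shape, order=3, mode="edge", anti_aliasing=new_h < h)
    if img.colorspace in ("GRAY", "RGB"):
        out = np.clip(out, 0.0, 1.0)
    return RasterImage(out, img.colorspace)


def pad_to_square_mean_gray(img: RasterImage) -> RasterImage:
    """Pad a GRAY image to a centered square with a mean-gray border.

    The side equals max(width, height); odd remainders put the extra
    row/column at the bottom/right.
    """
    if img.colorspace != "GRAY":
        raise ValueError("pad_to_square_mean_gray expects a GRAY image")
    h, w = img.height, img.width
    if h == w:
        return img
    side = max(h, w)
    mean = float(img.pixels.mean())
    out = np.full((side, side), mean, dtype=np.float64)
    top = (side - h) // 2
    left = (side - w) // 2
    out[top : top + h, left : left + w] = img.pixels
    return RasterImage(out, "GRAY")


def crop_empty_border(binary: np.ndarray) -> np.ndarray:
    """Crop a 0/1 image to the smallest bounding box of its set pixels.

    Raises :class:`DegenerateImageError` on an all-zero image (downstream,
    the fractal dimension is undefined in that case).
    """
    binary = np.asarray(binary)
    rows = np.flatnonzero(binary.any(axis=1))
    cols = np.flatnonzero(binary.any(axis=0))
    if rows.size == 0:
        raise DegenerateImageError("cannot crop an all-zero binary image")
    return binary[rows[0] : rows[-1] + 1, cols[0] : cols[-1] + 1]
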