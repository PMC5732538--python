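"""Radially averaged Fourier power spectrum: log-log slope and sigma.

The grayscale image is padded to a square with a mean-gray border, rescaled
to 1024 x 1024 by bicubic interpolation, and Fourier transformed.  The 2-D
power spectrum (squared modulus) is rotationally averaged into annuli at
integer frequencies 1..512 cycles/image.  Log10 power versus log10 frequency
is binned into 30 equal-width log-frequency bins spanning 5-256 cycles/image
and fitted by ordinary least squares; the slope is the "Fourier slope"
(around -2 for fine-detail-rich graphics, -3 for oil paintings) and sigma is
the mean squared residual of the binned points about the line (large when
specific frequencies dominate, e.g. periodic patterns).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocess import RasterImage, pad_to_square_mean_gray, resize_to_pixel_count, to_gray_luma

__all__ = ["RadialSpectrum", "SpectralFit", "radial_power_spectrum", "fit_slope_sigma", "fourier_slope_sigma"]

FFT_SIZE = 1024
FIT_RANGE = (5, 256)  # cycles/image, inclusive
N_LOG_BINS = 30
LOG_BASE = 10.0


@dataclass(frozen=True)
class RadialSpectrum:
    frequency: np.ndarray  # integers 1..512, cycles/image
    power: np.ndarray  # mean power per annulus, >= 0


@dataclass(frozen=True)
class SpectralFit:
    slope: float
    intercept: float
    sigma: float  # mean squared residual of the binned points


def radial_power_spectrum(img: RasterImage) -> RadialSpectrum:
    """Rotationally averaged power spectrum at frequencies 1..512 cycles/image."""
    gray = pad_to_square_mean_gray(to_gray_luma(img))
    if gray.height != FFT_SIZE:
        gray = resize_to_pixel_count(gray, FFT_SIZE * FFT_SIZE)
    px = gray.pixels
    n = px.shape[0]
    # real-input FFT covers the half plane; conjugate symmetry supplies the
    # rest, so columns 0 < v < n/2 count twice in the annulus averages
    power = np.abs(np.fft.rfft2(px)) ** 2
    u = np.fft.fftfreq(n) * n  # cycles/image, signed
    v = np.arange(n // 2 + 1)
    radius = np.rint(np.hypot(u[:, None], v[None, :])).astype(np.int64)
    mult = np.full(n // 2 + 1, 2.0)
    mult[0] = 1.0
    mult[-1] = 1.0
    weights = np.broadcast_to(mult, power.shape)
    max_f = n // 2
    sums = np.bincount(radius.ravel(), weights=(power * weights).ravel(), minlength=max_f + 1)
    counts = np.bincount(radius.ravel(), weights=weights.ravel(), minlength=max_f + 1)
    f = np.arange(1, max_f + 1)
    return RadialSpectrum(frequency=f, power=sums[1 : max_f + 1] / counts[1 : max_f + 1])


def fit_slope_sigma(spec: RadialSpectrum) -> SpectralFit:
    """Binned log-log OLS fit over 5-256 cycles/image.

    Frequencies are grouped into 30 equal-width bins in log10 frequency; the
    bin's point is (mean log10 f, mean log10 power) over its members, empty
    bins and zero-power frequencies dropped.  Returns NaN slope/sigma when
    fewer than 3 usable bins remain (e.g. a near-constant image).
    """
    lo, hi = FIT_RANGE
    in_range = (spec.frequency >= lo) & (spec.frequency <= hi) & (spec.power > 0)
    f = spec.frequency[in_range].astype(np.float64)
    p = spec.power[in_range]
    if f.size < 3:
        return SpectralFit(float("nan"), float("nan"), float("nan"))
    logf = np.log10(f)
    logp = np.log10(p)
    edges = np.linspace(np.log10(lo), np.log10(hi), N_LOG_BINS + 1)
    which = np.clip(np.searchsorted(edges, logf, side="right") - 1, 0, N_LOG_BINS - 1)
    xs, ys = [], []
    for b in range(N_LOG_BINS):
        m = which == b
        if m.any():
            xs.append(logf[m].mean())
            ys.append(logp[m].mean())
    if len(xs) < 3:
        return SpectralFit(float("nan"), float("nan"), float("nan"))
    x = np.array(xs)
    y = np.array(ys)
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    sigma = float(np.mean(resid**2))
    return SpectralFit(float(slope), float(intercept), sigma)


def fourier_slope_sigma(img: RasterImage) -> tuple[float, float]:
    """End-to-end Fourier slope and sigma of an image."""
    fit = fit_slope_sigma(radial_power_spectrum(img))
    return fit.slope, fit.sigma
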