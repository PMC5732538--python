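"""Run configuration: every tunable constant of the pipeline in one place.

Defaults reproduce the published analysis constants (24 orientations, the
10,000-response cap, 15-px border, 120,000 / 100,000-pixel analysis sizes,
16 HOG bins, pyramid levels 1-3, 1024x1024 Fourier size, 5-256 cycles/image
fit range, 20-80 px distance average) plus the documented implementation
choices (Gabor wavelength, Canny thresholds, 30 log-frequency bins,
alpha = 0.05).  A config round-trips through a flat ``key = value`` text
file and carries a stable hash for output provenance.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, fields
from pathlib import Path

__all__ = ["RunConfig"]


@dataclass(frozen=True)
class RunConfig:
    n_orientations: int = 24
    max_edge_responses: int = 10_000
    border_px: int = 15
    edge_analysis_pixels: int = 120_000
    phog_analysis_pixels: int = 100_000
    hog_bins: int = 16
    pyramid_levels: str = "1,2,3"
    fft_size: int = 1024
    fit_range_low: int = 5
    fit_range_high: int = 256
    d_average_low: int = 20
    d_average_high: int = 80
    gabor_wavelength: float = 8.0
    gabor_sigma_factor: float = 0.56
    canny_sigma: float = 1.0
    canny_low: float = 0.1
    canny_high: float = 0.2
    n_log_bins: int = 30
    alpha: float = 0.05

    def to_file(self, path: str | Path) -> None:
        lines = [f"{f.name} = {getattr(self, f.name)}" for f in fields(self)]
        Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        kwargs = {}
        types = {f.name: f.type for f in fields(cls)}
        for line in Path(path).read_text(encoding="utf-8").splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition("=")
            key = key.strip()
            value = value.strip()
            if key not in types:
                raise ValueError(f"unknown config key {key!r}")
            caster = {"int": int, "float": float, "str": str}[types[key]]
            kwargs[key] = caster(value)
        return cls(**kwargs)

    def digest(self) -> str:
        """Short stable hash over all key-value pairs, for provenance lines."""
        payload = ";".join(f"{k}={v}" for k, v in sorted(asdict(self).items()))
        return hashlib.sha256(payload.encode()).hexdigest()[:12]
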