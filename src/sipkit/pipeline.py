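"""End-to-end analysis: images -> SIP table -> group-comparison report."""

from __future__ import annotations

import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig
from .edge_entropy import accumulate_pairs, extract_edges, first_order_entropy, second_order_entropy
from .fourier import fourier_slope_sigma
from .fractal import fractal_dimension
from .phog import self_similarity
from .preprocess import DegenerateImageError, RasterImage, load_image
from .stats import SIP_MEASURES, compare_groups

__all__ = ["analyze_image", "analyze_directory", "compare_from_tables"]

log = logging.getLogger("sipkit")

IMAGE_SUFFIXES = (".png", ".jpg", ".jpeg", ".tif", ".tiff")


def analyze_image(
    img: RasterImage, measures: tuple[str, ...] = SIP_MEASURES
) -> dict[str, float]:
    """All requested SIP values of one image; undefined values come out NaN.

    ``measures`` restricts computation (second-order entropy dominates the
    cost: it accumulates ~10^8 ordered edge pairs per image).
    """
    out: dict[str, float] = {}
    need_edges = "first_order_entropy" in measures or "second_order_entropy" in measures
    if need_edges:
        try:
            edges = extract_edges(img)
        except DegenerateImageError as exc:
            log.info("edge extraction degenerate: %s", exc)
            edges = None
        if "first_order_entropy" in measures:
            out["first_order_entropy"] = first_order_entropy(edges) if edges and len(edges) else float("nan")
        if "second_order_entropy" in measures:
            if edges is not None and len(edges) >= 2:
                out["second_order_entropy"] = second_order_entropy(accumulate_pairs(edges))
            else:
                out["second_order_entropy"] = float("nan")
    if "self_similarity" in measures:
        try:
            out["self_similarity"] = self_similarity(img)
        except DegenerateImageError as exc:
            log.info("self-similarity degenerate: %s", exc)
            out["self_similarity"] = float("nan")
    if "fractal_dimension" in measures:
        out["fractal_dimension"] = fractal_dimension(img)
    if "fourier_slope" in measures or "fourier_sigma" in measures:
        slope, sigma = fourier_slope_sigma(img)
        if "fourier_slope" in measures:
            out["fourier_slope"] = slope
        if "fourier_sigma" in measures:
            out["fourier_sigma"] = sigma
    return out


def analyze_directory(
    image_dir: str | Path,
    out_csv: str | Path | None = None,
    config: RunConfig | None = None,
    measures: tuple[str, ...] = SIP_MEASURES,
) -> pd.DataFrame:
    """One SIP row per readable image in ``image_dir`` (recursive).

    Unreadable files are logged and skipped; per-image failures never abort
    the run.  When ``out_csv`` is given the table is written with a
    provenance header line carrying the tool version and config hash.
    """
    config = config or RunConfig()
    image_dir = Path(image_dir)
    paths = sorted(p for p in image_dir.rglob("*") if p.suffix.lower() in IMAGE_SUFFIXES)
    if not paths:
        raise ValueError(f"no readable images found under {image_dir}")
    rows = []
    for path in paths:
        try:
            img = load_image(path)
        except IOError as exc:
            log.warning("skipping unreadable file %s: %s", path, exc)
            continue
        t0 = time.perf_counter()
        values = analyze_image(img, measures=measures)
        log.info("%s analyzed in %.2f s", path.name, time.perf_counter() - t0)
        group = path.parent.name if path.parent != image_dir else ""
        rows.append({"image_id": path.stem, "group": group, **values})
    table = pd.DataFrame(rows)
    if out_csv is not None:
        _write_with_provenance(table, out_csv, config)
    return table


def _write_with_provenance(table: pd.DataFrame, path: str | Path, config: RunConfig) -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# sipkit {__version__} config {config.digest()}\n")
        table.to_csv(fh, index=False)


def read_sip_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def compare_from_tables(
    sip_table: pd.DataFrame,
    grouping: pd.DataFrame | None = None,
    out_dir: str | Path | None = None,
    config: RunConfig | None = None,
    artist_groups: list[str] | None = None,
    control_groups: list[str] | None = None,
):
    """Group-comparison report from a SIP table and an optional grouping table.

    ``grouping`` (columns image_id, group) overrides the group column of the
    SIP table; every image_id in the grouping must have a SIP row.  Writes
    omnibus, pairwise, deviation and summary tables to ``out_dir`` if given.
    """
    config = config or RunConfig()
    table = sip_table.copy()
    if grouping is not None:
        missing = set(grouping["image_id"]) - set(table["image_id"])
        if missing:
            raise ValueError(f"grouping refers to image_ids without SIP rows: {sorted(missing)[:10]}")
        table = table.drop(columns=["group"], errors="ignore").merge(
            grouping[["image_id", "group"]], on="image_id", how="inner"
        )
    report = compare_groups(
        table, artist_groups=artist_groups, control_groups=control_groups, alpha=config.alpha
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        _write_with_provenance(report.omnibus.reset_index(), out_dir / "omnibus.csv", config)
        _write_with_provenance(report.pairwise, out_dir / "pairwise.csv", config)
        if report.deviation is not None:
            _write_with_provenance(report.deviation.reset_index(), out_dir / "deviation.csv", config)
        from .stats import group_summary

        measures = [m for m in SIP_MEASURES if m in table.columns]
        summaries = []
        for measure in measures:
            groups = {lab: sub[measure].to_numpy() for lab, sub in table.groupby("group", sort=False)}
            groups = {k: v[~np.isnan(v)] for k, v in groups.items()}
            groups = {k: v for k, v in groups.items() if v.size}
            s = group_summary(groups)
            s.insert(0, "measure", measure)
            summaries.append(s)
        _write_with_provenance(pd.concat(summaries, ignore_index=True), out_dir / "summaries.csv", config)
    return report
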