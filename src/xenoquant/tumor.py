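"""Image-based tumor burden and metastasis scoring.

Fluorescently labeled cancer cells are injected into the larval yolk
sac; at endpoint each larva is imaged and scored for (i) the tumor area
inside an elliptical yolk region of interest and (ii) the number of
labeled cell spots dispersed beyond the yolk.  A larva with at least
``min_cells`` (default 5) dispersed cells is metastasis-positive.
Tumor area is measured both automatically (threshold segmentation) and
manually (polygon tracing); downstream plots use the mean of the two.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu
from skimage.measure import label

NO_CELLS = "no_cells"
LOCALIZED = "localized"
INVADED = "invaded"


class NoContrastError(ValueError):
    """The region of interest is uniformly saturated; no threshold exists."""


@dataclass(frozen=True)
class LarvaImage:
    pixels: np.ndarray
    magnification_tag: str = ""


@dataclass(frozen=True)
class YolkRoi:
    """Elliptical yolk-sac region, pixel coordinates (x right, y down)."""

    center: tuple  # (x, y)
    radii: tuple   # (rx, ry)

    def __post_init__(self):
        if self.radii[0] <= 0 or self.radii[1] <= 0:
            raise ValueError("ROI radii must be positive")

    def mask(self, shape) -> np.ndarray:
        h, w = shape
        cx, cy = self.center
        rx, ry = self.radii
        yy, xx = np.ogrid[:h, :w]
        m = ((xx - cx) / rx) ** 2 + ((yy - cy) / ry) ** 2 <= 1.0
        if not m.any():
            raise ValueError("ROI does not intersect image bounds")
        return m


@dataclass(frozen=True)
class MetastasisConfig:
    """Scoring parameters.

    ``min_cells`` dispersed cells call a larva metastasis-positive.
    Spots outside the ROI count only when their area lies within
    [min_spot_area, max_spot_area].  ``min_contrast`` is the smallest
    intensity range within the ROI treated as real signal; below it the
    image is scored empty instead of thresholding noise.
    """

    min_cells: int = 5
    min_spot_area: int = 4
    max_spot_area: int = 400
    threshold_mode: str = "otsu"  # or "fixed"
    threshold_value: float | None = None
    min_contrast: float = 50.0

    def __post_init__(self):
        if self.min_cells < 1:
            raise ValueError("min_cells must be >= 1")
        if not (0 < self.min_spot_area < self.max_spot_area):
            raise ValueError("require 0 < min_spot_area < max_spot_area")
        if self.threshold_mode == "fixed" and self.threshold_value is None:
            raise ValueError("fixed threshold mode needs threshold_value")


@dataclass(frozen=True)
class EmbryoPhenotype:
    embryo_id: str
    phenotype: str          # tail-test class or qPCR genotype call
    cell_line: str = "other"
    experiment_set: int = 1
    tumor_area: float = 0.0
    dispersed_cell_count: int = 0
    status: str = NO_CELLS
    metastasis_positive: bool = False


def _pixels(img) -> np.ndarray:
    arr = img.pixels if isinstance(img, LarvaImage) else np.asarray(img)
    arr = np.asarray(arr, dtype=float)
    if arr.ndim != 2 or arr.size == 0:
        raise ValueError("image must be a non-empty 2-D grayscale array")
    if not np.all(np.isfinite(arr)) or arr.min() < 0:
        raise ValueError("intensities must be finite and non-negative")
    return arr


def _threshold(values: np.ndarray, cfg: MetastasisConfig) -> float | None:
    """Pick a foreground threshold; None means 'nothing to segment'."""
    if cfg.threshold_mode == "fixed":
        return float(cfg.threshold_value)
    lo, hi = float(values.min()), float(values.max())
    if hi == lo:
        if hi == 0.0:
            return None  # blank image, area 0
        raise NoContrastError("no contrast: uniform saturated region")
    if hi - lo < cfg.min_contrast:
        return None  # noise-only region, score empty
    return float(threshold_otsu(values))


def segment_tumor_area(img, roi: YolkRoi, cfg: MetastasisConfig | None = None):
    """Threshold-segment the yolk tumor; returns (area_px, binary mask).

    The threshold (Otsu by default) is derived from the ROI pixels and
    applied to the whole image; the tumor area is the total foreground
    of connected components that intersect the ROI, so a mass spilling
    over the ROI boundary is still counted in full.  Deterministic for a
    fixed image and configuration.
    """
    cfg = cfg or MetastasisConfig()
    arr = _pixels(img)
    roi_mask = roi.mask(arr.shape)
    thr = _threshold(arr[roi_mask], cfg)
    if thr is None:
        return 0, np.zeros(arr.shape, dtype=bool)
    fg = arr > thr
    labels = label(fg)
    in_roi = np.unique(labels[roi_mask & fg])
    keep = np.isin(labels, in_roi[in_roi > 0]) & fg
    return int(keep.sum()), keep


def polygon_area(vertices) -> float:
    """Area enclosed by a traced polygon (shoelace formula).

    Orientation-independent; vertices are (x, y) pairs in order.
    """
    pts = np.asarray(vertices, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 3 or pts.shape[1] != 2:
        raise ValueError("polygon needs at least 3 (x, y) vertices")
    x, y = pts[:, 0], pts[:, 1]
    return float(abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))) / 2.0)


def combine_area(manual: float, automatic: float) -> float:
    """Average the manual (polygon) and automatic (threshold) areas."""
    if manual < 0 or automatic < 0:
        raise ValueError("areas must be non-negative")
    return (manual + automatic) / 2.0


def count_dispersed_cells(img, roi: YolkRoi,
                          cfg: MetastasisConfig | None = None) -> int:
    """Count labeled cell spots strictly outside the yolk ROI.

    Connected components with no pixel inside the ROI and an area within
    the configured spot bounds are counted; the size gate rejects single
    noise pixels and large debris.
    """
    cfg = cfg or MetastasisConfig()
    arr = _pixels(img)
    roi_mask = roi.mask(arr.shape)
    thr = _threshold(arr, cfg)
    if thr is None:
        return 0
    fg = arr > thr
    labels = label(fg)
    touching_roi = set(np.unique(labels[roi_mask & fg]))
    count = 0
    for lab in range(1, labels.max() + 1):
        if lab in touching_roi:
            continue
        area = int((labels == lab).sum())
        if cfg.min_spot_area <= area <= cfg.max_spot_area:
            count += 1
    return count


def classify_embryo(tumor_area: float, dispersed: int,
                    cfg: MetastasisConfig | None = None):
    """Score one larva; returns (status, metastasis_positive).

    No signal anywhere → ``no_cells``; any signal with fewer than
    ``min_cells`` dispersed spots → ``localized`` (negative); at least
    ``min_cells`` dispersed → ``invaded`` (positive).
    """
    cfg = cfg or MetastasisConfig()
    if tumor_area < 0 or dispersed < 0:
        raise ValueError("inputs must be non-negative")
    if dispersed >= cfg.min_cells:
        return INVADED, True
    if tumor_area == 0 and dispersed == 0:
        return NO_CELLS, False
    return LOCALIZED, False


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal half-up rounding (the convention of the cohort tables)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def cohort_table(phenotypes, metastasis_denominator: str = "with_signal",
                 ) -> pd.DataFrame:
    """Per (cell line, phenotype) tumorigenicity/metastasis tabulation.

    Tumorigenicity % is 100 × localized / total injected, half-up to one
    decimal.  The metastasis denominator is configurable because cohort
    accounting conventions differ: ``"with_signal"`` (default) uses
    embryos with any tumor signal, ``"total"`` all injected embryos.
    Percentages of an empty denominator are reported absent (NaN), never
    as 0.
    """
    if metastasis_denominator not in ("with_signal", "total"):
        raise ValueError("metastasis_denominator must be 'with_signal' or 'total'")
    records = [p if isinstance(p, dict) else {
        "cell_line": p.cell_line, "phenotype": p.phenotype,
        "status": p.status, "metastasis_positive": p.metastasis_positive,
    } for p in phenotypes]
    df = pd.DataFrame(records)
    rows = []
    for (cell_line, phenotype), grp in df.groupby(["cell_line", "phenotype"],
                                                  sort=False):
        n = len(grp)
        n_no = int((grp["status"] == NO_CELLS).sum())
        n_loc = int((grp["status"] == LOCALIZED).sum())
        n_inv = int((grp["status"] == INVADED).sum())
        n_pos = int(grp["metastasis_positive"].sum())
        tumorigenicity = round_half_up(100.0 * n_loc / n) if n else math.nan
        denom = (n_loc + n_inv) if metastasis_denominator == "with_signal" else n
        metastasis = round_half_up(100.0 * n_pos / denom) if denom else math.nan
        rows.append({"cell_line": cell_line, "phenotype": phenotype,
                     "n_total": n, "n_no_cells": n_no, "n_localized": n_loc,
                     "n_invaded": n_inv, "n_metastasis_positive": n_pos,
                     "tumorigenicity_pct": tumorigenicity,
                     "metastasis_pct": metastasis})
    out = pd.DataFrame(rows, columns=["cell_line", "phenotype", "n_total",
                                      "n_no_cells", "n_localized", "n_invaded",
                                      "n_metastasis_positive",
                                      "tumorigenicity_pct", "metastasis_pct"])
    out.attrs["metastasis_denominator"] = metastasis_denominator
    return out
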