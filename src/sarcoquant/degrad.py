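"""Staining-intensity quantification for knockdown/degradation comparisons.

Procedure per image: estimate the background as the mean over a band-free
rectangle, then place a fixed number of equally sized rectangles on band
loci (seeded, deterministic) and record each rectangle's
background-subtracted mean. Animals are the unit of analysis: ROI means
are averaged per image, images per animal, and groups are compared by
percent change and a Mann-Whitney test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np

from .stats import MannWhitneyResult, mann_whitney

logger = logging.getLogger(__name__)

__all__ = [
    "RoiIntensityTable",
    "DegradComparison",
    "estimate_image_background",
    "sample_band_rois",
    "compare_groups",
    "aggregate_animal_means",
]

Rect = Tuple[int, int, int, int]  # (row0, col0, row1, col1), half-open


@dataclass(frozen=True)
class RoiIntensityTable:
    """Background-subtracted rectangle means for one image."""

    animal_id: str
    genotype: str  # "control" or "treated"
    channel: str
    values: np.ndarray  # a.u., one per rectangle
    background_mean: float
    roi_size: Tuple[int, int]  # (rows, cols), pixels
    n_requested: int

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))


@dataclass(frozen=True)
class DegradComparison:
    percent_change: float  # 100 * (1 - mean_treated / mean_control)
    test: Optional[MannWhitneyResult]
    mean_control: float
    mean_treated: float
    n_control: int
    n_treated: int


def estimate_image_background(image: np.ndarray, roi: Rect) -> float:
    """Mean pixel intensity over a rectangle placed on a band-free area."""
    r0, c0, r1, c1 = roi
    if not (0 <= r0 < r1 <= image.shape[0] and 0 <= c0 < c1 <= image.shape[1]):
        raise ValueError(f"background ROI {roi} outside image {image.shape}")
    return float(np.mean(image[r0:r1, c0:c1]))


def sample_band_rois(
    image: np.ndarray,
    band_columns: Sequence[float],
    background: float,
    n_rois: int = 100,
    roi_size: Tuple[int, int] = (10, 5),
    seed: int = 0,
    row_range: Optional[Tuple[int, int]] = None,
    background_roi: Optional[Rect] = None,
    animal_id: str = "",
    genotype: str = "",
    channel: str = "",
) -> RoiIntensityTable:
    """Place ``n_rois`` equally sized rectangles on band loci, seeded.

    ``band_columns`` are the band centre columns (e.g. detected peak
    positions converted to pixels); rectangles are centred on a randomly
    chosen band with a random row inside ``row_range`` and never overlap
    ``background_roi``. Bands are reused (sampling with replacement). If
    fewer than ``n_rois`` placements fit, the shorter table is returned
    with a warning.
    """
    band_columns = np.asarray(band_columns, dtype=float)
    if band_columns.size == 0:
        raise ValueError("no band columns supplied")
    h, w = roi_size
    if h <= 0 or w <= 0:
        raise ValueError("roi_size must be positive")
    rows = row_range if row_range is not None else (0, image.shape[0])
    lo = max(rows[0], 0)
    hi = min(rows[1], image.shape[0])
    if hi - lo < h:
        raise ValueError("row_range too small for the ROI height")
    rng = np.random.default_rng(seed)
    values = []
    attempts = 0
    while len(values) < n_rois and attempts < 50 * n_rois:
        attempts += 1
        col_center = float(rng.choice(band_columns))
        c0 = int(round(col_center)) - w // 2
        r0 = int(rng.integers(lo, hi - h + 1))
        rect = (r0, c0, r0 + h, c0 + w)
        if rect[1] < 0 or rect[3] > image.shape[1]:
            continue
        if background_roi is not None and not _disjoint(rect, background_roi):
            continue
        values.append(float(np.mean(image[rect[0]:rect[2], rect[1]:rect[3]])) - background)
    if len(values) < n_rois:
        logger.warning("only %d of %d ROIs placed", len(values), n_rois)
    return RoiIntensityTable(
        animal_id, genotype, channel, np.asarray(values), background,
        (h, w), n_rois,
    )


def _disjoint(a: Rect, b: Rect) -> bool:
    return a[2] <= b[0] or b[2] <= a[0] or a[3] <= b[1] or b[3] <= a[1]


def aggregate_animal_means(tables: Sequence[RoiIntensityTable]) -> dict[str, float]:
    """ROI means -> image mean -> animal mean; refuses mixed rectangle sizes."""
    sizes = {t.roi_size for t in tables}
    if len(sizes) > 1:
        raise ValueError(f"mixed ROI sizes across images: {sorted(sizes)}")
    per_animal: dict[str, list[float]] = {}
    for t in tables:
        per_animal.setdefault(t.animal_id, []).append(t.mean)
    return {animal: float(np.mean(v)) for animal, v in per_animal.items()}


def compare_groups(
    control_means: Sequence[float], treated_means: Sequence[float]
) -> DegradComparison:
    """Percent intensity change between groups of per-animal means."""
    control = np.asarray(control_means, dtype=float)
    treated = np.asarray(treated_means, dtype=float)
    if control.size == 0 or treated.size == 0:
        raise ValueError("both groups need >= 1 animal")
    mc = float(np.mean(control))
    mt = float(np.mean(treated))
    if mc <= 0:
        raise ValueError(f"control group mean must be > 0, got {mc:.4g}")
    percent = 100.0 * (1.0 - mt / mc)
    if min(control.size, treated.size) < 2:
        logger.warning("a group has < 2 animals; Mann-Whitney test skipped")
        test = None
    else:
        test = mann_whitney(control, treated)
    return DegradComparison(percent, test, mc, mt, int(control.size), int(treated.size))
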