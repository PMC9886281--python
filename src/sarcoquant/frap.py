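"""FRAP quantification from ROI means.

The per-frame ratio is (bleached - background) / (unbleached - background);
on top of that raw ratio a double-normalised recovery fraction
(R(t) - R(0+)) / (R_pre - R(0+)) is reported, which is robust to bleach
depth. R(0+) is the ratio at the first post-bleach frame, R_pre the mean
ratio over pre-bleach frames. No acquisition-bleaching correction is
applied by default.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Tuple

import numpy as np

logger = logging.getLogger(__name__)

__all__ = ["FrapRecord", "NoBleachError", "roi_mean", "quantify_frap", "recovery_at"]

Rect = Tuple[int, int, int, int]  # (row0, col0, row1, col1), half-open


class NoBleachError(ValueError):
    """Raised when the pre-bleach and first post-bleach ratios are indistinguishable."""


@dataclass(frozen=True)
class FrapRecord:
    """Per-frame FRAP quantities; time is 0 at the first post-bleach frame."""

    time: np.ndarray  # s
    i_bleached: np.ndarray
    i_unbleached: np.ndarray
    i_background: np.ndarray
    ratio: np.ndarray
    valid: np.ndarray  # frames where unbleached - background > 0
    recovery_fraction: np.ndarray  # NaN before the bleach
    prebleach_ratio: float
    bleach_frame_index: int

    @property
    def final_recovery(self) -> float:
        return float(self.recovery_fraction[-1])


def roi_mean(frame: np.ndarray, rect: Rect) -> float:
    r0, c0, r1, c1 = rect
    if not (0 <= r0 < r1 <= frame.shape[0] and 0 <= c0 < c1 <= frame.shape[1]):
        raise ValueError(f"ROI {rect} outside field {frame.shape}")
    return float(np.mean(frame[r0:r1, c0:c1]))


def _disjoint(a: Rect, b: Rect) -> bool:
    return a[2] <= b[0] or b[2] <= a[0] or a[3] <= b[1] or b[3] <= a[1]


def quantify_frap(
    movie: np.ndarray,
    roi_bleached: Rect,
    roi_unbleached: Rect,
    roi_background: Rect,
    bleach_frame_index: int,
    frame_interval: float,
) -> FrapRecord:
    """Three-ROI FRAP quantification of a (frames, rows, cols) movie.

    The ROIs must be pairwise disjoint and inside the field, and at least
    one pre-bleach frame must exist. Frames where the background-subtracted
    unbleached mean is non-positive are flagged invalid. Raises
    :class:`NoBleachError` when no bleach is detectable.
    """
    rois = (roi_bleached, roi_unbleached, roi_background)
    for i in range(3):
        for j in range(i + 1, 3):
            if not _disjoint(rois[i], rois[j]):
                raise ValueError(f"ROIs {rois[i]} and {rois[j]} overlap")
    n_frames = movie.shape[0]
    if not 1 <= bleach_frame_index < n_frames:
        raise ValueError("need >= 1 pre-bleach frame and a post-bleach movie")
    ib = np.array([roi_mean(movie[k], roi_bleached) for k in range(n_frames)])
    iu = np.array([roi_mean(movie[k], roi_unbleached) for k in range(n_frames)])
    ig = np.array([roi_mean(movie[k], roi_background) for k in range(n_frames)])
    denom = iu - ig
    valid = denom > 0
    if not np.all(valid):
        logger.warning("%d frames have non-positive unbleached-background signal",
                       int(np.sum(~valid)))
    ratio = np.full(n_frames, np.nan)
    ratio[valid] = (ib[valid] - ig[valid]) / denom[valid]
    pre = ratio[:bleach_frame_index]
    r_pre = float(np.nanmean(pre))
    r0 = float(ratio[bleach_frame_index])
    drop = r_pre - r0
    if not np.isfinite(drop) or drop <= 1e-9 * max(abs(r_pre), 1.0):
        raise NoBleachError(
            f"no bleach detected: pre-bleach ratio {r_pre:.6g} vs first "
            f"post-bleach ratio {r0:.6g}"
        )
    recovery = np.full(n_frames, np.nan)
    post = slice(bleach_frame_index, None)
    recovery[post] = (ratio[post] - r0) / drop
    time = (np.arange(n_frames) - bleach_frame_index) * frame_interval
    return FrapRecord(time, ib, iu, ig, ratio, valid, recovery, r_pre,
                      bleach_frame_index)


def recovery_at(record: FrapRecord, t: float) -> float:
    """Linear interpolation of the recovery fraction at post-bleach time ``t`` (s)."""
    post = record.time >= 0
    times = record.time[post]
    values = record.recovery_fraction[post]
    if not times[0] <= t <= times[-1]:
        raise ValueError(f"t={t} s outside post-bleach range [{times[0]}, {times[-1]}]")
    return float(np.interp(t, times, values))
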