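"""Band-intensity decay with imaging depth.

Per z-slice, a myofibril line ROI is turned into a profile and pushed
through the band pipeline (background subtraction, peak detection,
Gaussian fits, analytic areas); the mean band area per slice against depth
is then fitted with a bare exponential I(z) = I0 * exp(-z / lambda) —
no additive offset — and decay lengths are compared between label groups
with a ratio of means and a Mann-Whitney test.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
from scipy.optimize import curve_fit
from skimage.measure import profile_line

from . import profiles as _profiles
from .profiles import BandWindowError, LineProfile
from .stats import MannWhitneyResult, mann_whitney

logger = logging.getLogger(__name__)

__all__ = [
    "DepthSeries",
    "DepthDecayFit",
    "DecayComparison",
    "extract_profile",
    "band_intensity_vs_depth",
    "fit_decay",
    "compare_decay_lengths",
]


@dataclass(frozen=True)
class DepthSeries:
    """Mean integrated band area per z-slice for one myofibril."""

    myofibril_id: str
    label: str
    depths: np.ndarray  # µm, strictly increasing
    intensities: np.ndarray  # a.u.
    excluded_slices: tuple = ()

    def __post_init__(self) -> None:
        d = np.asarray(self.depths, dtype=float)
        i = np.asarray(self.intensities, dtype=float)
        if d.size != i.size:
            raise ValueError("depths and intensities lengths differ")
        if d.size and np.any(np.diff(d) <= 0):
            raise ValueError("depths must be strictly increasing")
        object.__setattr__(self, "depths", d)
        object.__setattr__(self, "intensities", i)

    def __len__(self) -> int:
        return int(self.depths.size)


@dataclass(frozen=True)
class DepthDecayFit:
    i0: float
    decay_length: float  # µm
    rms_residual: float
    n_points: int


@dataclass(frozen=True)
class DecayComparison:
    ratio: float  # mean(lambda_a) / mean(lambda_b)
    test: Optional[MannWhitneyResult]
    n_a: int
    n_b: int


def extract_profile(
    image: np.ndarray,
    polyline: np.ndarray,
    pixel_size: float,
    linewidth: int = 1,
    channel: str = "",
    source_id: str = "",
) -> LineProfile:
    """Sample an image along a polyline of (row, col) vertices.

    Averages over ``linewidth`` pixels perpendicular to the line (like a
    wide line selection). Positions are path length in µm at pixel centres.
    """
    polyline = np.asarray(polyline, dtype=float)
    if polyline.ndim != 2 or polyline.shape[0] < 2 or polyline.shape[1] != 2:
        raise ValueError("polyline must be an (n>=2, 2) array of (row, col) points")
    segments = [
        profile_line(
            image, tuple(polyline[i]), tuple(polyline[i + 1]),
            linewidth=linewidth, order=1, mode="reflect", reduce_func=np.mean,
        )
        for i in range(polyline.shape[0] - 1)
    ]
    # drop the duplicated joint sample between consecutive segments
    values = segments[0]
    for seg in segments[1:]:
        values = np.concatenate([values, seg[1:]])
    positions = (np.arange(values.size) + 0.5) * pixel_size
    return LineProfile(positions, values, channel=channel, pixel_size=pixel_size,
                       source_id=source_id)


def band_intensity_vs_depth(
    stack: np.ndarray,
    rois: Union[np.ndarray, Sequence[np.ndarray]],
    pixel_size: float,
    z_step: float,
    myofibril_id: str = "",
    label: str = "",
    linewidth: int = 1,
    background_fraction: float = 0.35,
    min_prominence: float = 0.2,
    min_separation: Optional[float] = None,
) -> DepthSeries:
    """Mean integrated band area per slice of a z-stack along a myofibril ROI.

    ``rois`` is either a single polyline applied to every slice or one
    polyline per slice. Slices where no band survives detection and
    fitting are excluded (logged), not imputed.
    """
    n_slices = stack.shape[0]
    if isinstance(rois, np.ndarray) and rois.ndim == 2:
        roi_list = [rois] * n_slices
    else:
        roi_list = list(rois)
        if len(roi_list) != n_slices:
            raise ValueError(f"need one ROI per slice: {len(roi_list)} != {n_slices}")
    depths, means, excluded = [], [], []
    for k in range(n_slices):
        prof = extract_profile(
            stack[k], roi_list[k], pixel_size, linewidth=linewidth,
            source_id=f"{myofibril_id}/z{k}",
        )
        _, corrected = _profiles.subtract_background(prof, background_fraction)
        peaks = _profiles.find_bands(corrected, min_prominence, min_separation)
        areas = []
        for p in peaks.positions:
            try:
                fit = _profiles.fit_band(corrected, p, neighbor_peaks=peaks.positions)
            except BandWindowError:
                continue
            if fit.converged and fit.amplitude > 0:
                areas.append(_profiles.integrate_band(fit))
        if areas:
            depths.append(k * z_step)
            means.append(float(np.mean(areas)))
        else:
            excluded.append(k)
            logger.info("slice %d of %s: no bands detected, excluded", k, myofibril_id)
    if not depths and excluded:
        logger.warning("myofibril %s: no bands in any slice", myofibril_id)
    return DepthSeries(myofibril_id, label, np.array(depths), np.array(means),
                       tuple(excluded))


def _exp_model(z: np.ndarray, i0: float, lam: float) -> np.ndarray:
    return i0 * np.exp(-z / lam)


def fit_decay(series: Union[DepthSeries, tuple]) -> DepthDecayFit:
    """Nonlinear least squares of I(z) = I0 exp(-z/lambda), log-linear initialised."""
    if isinstance(series, DepthSeries):
        z, y = series.depths, series.intensities
    else:
        z, y = (np.asarray(v, dtype=float) for v in series)
    if z.size < 3:
        raise ValueError(f"decay fit needs >= 3 points, got {z.size}")
    if np.all(y == y[0]):
        raise ValueError("decay fit is degenerate: intensities all equal")
    pos = y > 0
    if not np.any(pos):
        raise ValueError("decay fit needs at least one positive intensity")
    if np.count_nonzero(pos) >= 2 and np.ptp(z[pos]) > 0:
        slope, logc = np.polyfit(z[pos], np.log(y[pos]), 1)
        lam0 = -1.0 / slope if slope < 0 else 10.0 * float(np.ptp(z))
        i00 = math.exp(logc)
    else:
        lam0 = float(np.ptp(z)) or 1.0
        i00 = float(np.max(y))
    popt, _ = curve_fit(_exp_model, z, y, p0=(i00, lam0), maxfev=5000)
    i0, lam = float(popt[0]), float(popt[1])
    if not (i0 > 0 and lam > 0):
        raise RuntimeError(f"decay fit diverged: I0={i0:.4g}, lambda={lam:.4g}")
    rms = float(np.sqrt(np.mean((y - _exp_model(z, i0, lam)) ** 2)))
    return DepthDecayFit(i0, lam, rms, int(z.size))


def compare_decay_lengths(
    group_a: Sequence[float], group_b: Sequence[float]
) -> DecayComparison:
    """Ratio of group-mean decay lengths plus a two-sided Mann-Whitney test.

    Groups hold one decay length per animal. With fewer than 2 animals in
    either group the ratio is still reported but the test is skipped.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    ratio = float(np.mean(a) / np.mean(b))
    if min(a.size, b.size) < 2:
        logger.warning("a group has < 2 animals; Mann-Whitney test skipped")
        return DecayComparison(ratio, None, int(a.size), int(b.size))
    return DecayComparison(ratio, mann_whitney(a, b), int(a.size), int(b.size))
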