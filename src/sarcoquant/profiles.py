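"""Band analysis on 1-D intensity profiles.

The measurement chain is: optional Gaussian smoothing, linear background
subtraction fitted on the lowest-intensity quantile, strict local-maximum
peak detection with prominence and separation thresholds, per-band Gaussian
fitting on a local window, and analytic band-area integration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy import signal
from scipy.ndimage import gaussian_filter1d
from scipy.optimize import curve_fit

__all__ = [
    "LineProfile",
    "BackgroundModel",
    "PeakSet",
    "BandFit",
    "BandWindowError",
    "subtract_background",
    "find_bands",
    "fit_band",
    "integrate_band",
    "smooth_profile",
]

_SQRT_2PI = math.sqrt(2.0 * math.pi)
#: FWHM of a Gaussian in units of sigma.
_FWHM_PER_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))


class BandWindowError(ValueError):
    """Raised when a band's fit window contains too few samples."""


@dataclass(frozen=True)
class LineProfile:
    """One channel of one scan line: positions in µm against intensities in a.u.

    Positions must be strictly increasing and uniformly spaced (relative
    tolerance 1e-6) with at least 8 samples.
    """

    positions: np.ndarray
    intensities: np.ndarray
    channel: str = ""
    pixel_size: float = 0.0
    source_id: str = ""

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        inten = np.asarray(self.intensities, dtype=float)
        if pos.ndim != 1 or inten.ndim != 1:
            raise ValueError("positions and intensities must be 1-D")
        if pos.size != inten.size:
            raise ValueError(
                f"length mismatch: {pos.size} positions vs {inten.size} intensities"
            )
        if pos.size < 8:
            raise ValueError(f"profile needs >= 8 samples, got {pos.size}")
        steps = np.diff(pos)
        if np.any(steps <= 0):
            raise ValueError("positions must be strictly increasing")
        step = float(np.median(steps))
        if np.any(np.abs(steps - step) > 1e-6 * max(abs(step), 1e-300)):
            raise ValueError("positions must be uniformly spaced (rel tol 1e-6)")
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "intensities", inten)
        if not self.pixel_size:
            object.__setattr__(self, "pixel_size", step)

    def __len__(self) -> int:
        return int(self.positions.size)

    def with_intensities(self, intensities: np.ndarray) -> "LineProfile":
        return replace(self, intensities=np.asarray(intensities, dtype=float))


@dataclass(frozen=True)
class BackgroundModel:
    """Linear background fitted to the lowest-intensity quantile of a profile."""

    slope: float
    intercept: float
    fraction: float
    points_used: np.ndarray

    def evaluate(self, positions: np.ndarray) -> np.ndarray:
        return self.slope * np.asarray(positions, dtype=float) + self.intercept


@dataclass(frozen=True)
class PeakSet:
    """Detected band positions (µm, ascending) and their heights."""

    positions: np.ndarray
    heights: np.ndarray
    min_prominence: float
    min_separation: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "positions", np.asarray(self.positions, dtype=float))
        object.__setattr__(self, "heights", np.asarray(self.heights, dtype=float))

    def __len__(self) -> int:
        return int(self.positions.size)


@dataclass(frozen=True)
class BandFit:
    """Single-Gaussian band fit A*exp(-(x-mu)^2 / (2 sigma^2))."""

    amplitude: float
    center: float
    sigma: float
    rms_residual: float
    converged: bool
    n_window: int = 0

    @property
    def area(self) -> float:
        """Analytic area under the fitted Gaussian, A*sigma*sqrt(2*pi)."""
        return self.amplitude * self.sigma * _SQRT_2PI


def subtract_background(
    profile: LineProfile, fraction: float = 0.35
) -> tuple[BackgroundModel, LineProfile]:
    """Fit a line to the ``ceil(fraction*n)`` smallest-intensity samples and subtract it.

    Selection is by intensity rank (stable order for ties), the fit is
    ordinary least squares of intensity on position over the selected
    samples only, and the corrected profile is not clipped at zero.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError(f"fraction must be in (0, 1), got {fraction}")
    n = len(profile)
    m = int(math.ceil(fraction * n))
    if m < 2:
        raise ValueError(
            f"background fit needs >= 2 selected points, got {m} "
            f"(n={n}, fraction={fraction})"
        )
    order = np.argsort(profile.intensities, kind="stable")
    idx = np.sort(order[:m])
    x = profile.positions[idx]
    y = profile.intensities[idx]
    if np.ptp(x) == 0.0:
        raise ValueError("degenerate background fit: selected positions all equal")
    slope, intercept = np.polyfit(x, y, 1)
    model = BackgroundModel(float(slope), float(intercept), fraction, idx)
    corrected = profile.with_intensities(
        profile.intensities - model.evaluate(profile.positions)
    )
    return model, corrected


def find_bands(
    profile: LineProfile,
    min_prominence: float = 0.2,
    min_separation: Optional[float] = None,
) -> PeakSet:
    """Detect local maxima on a background-corrected profile.

    A sample qualifies if it is a local maximum (plateaus of equal values
    count once, at their midpoint), its topographic prominence is >=
    ``min_prominence`` times the profile maximum, and it is at least
    ``min_separation`` µm from every retained higher peak (ties resolved
    to the leftmost). ``min_separation`` defaults to 10 pixels. An empty
    result is returned, never raised.
    """
    if min_separation is None:
        min_separation = 10.0 * profile.pixel_size
    y = profile.intensities
    x = profile.positions
    empty = PeakSet(np.empty(0), np.empty(0), min_prominence, float(min_separation))
    ymax = float(np.max(y)) if y.size else 0.0
    if ymax <= 0.0:
        return empty
    cand = signal.find_peaks(y)[0]
    if cand.size == 0:
        return empty
    prominences = signal.peak_prominences(y, cand)[0]
    keep = prominences >= min_prominence * ymax
    cand = cand[keep]
    if cand.size == 0:
        return empty
    # Greedy separation culling: highest first, leftmost on height ties.
    order = sorted(range(cand.size), key=lambda i: (-y[cand[i]], x[cand[i]]))
    accepted: list[int] = []
    for i in order:
        xi = x[cand[i]]
        if all(abs(xi - x[cand[j]]) >= min_separation for j in accepted):
            accepted.append(i)
    sel = np.sort(cand[accepted])
    return PeakSet(x[sel], y[sel], min_prominence, float(min_separation))


def _gauss(x: np.ndarray, amplitude: float, center: float, sigma: float) -> np.ndarray:
    return amplitude * np.exp(-((x - center) ** 2) / (2.0 * sigma**2))


def _half_max_crossing(
    x: np.ndarray, y: np.ndarray, peak_idx: int, half: float, direction: int
) -> float:
    """Position where the profile first drops below ``half`` walking from the peak."""
    i = peak_idx
    while 0 <= i + direction < x.size and y[i + direction] >= half:
        i += direction
    j = i + direction
    if not 0 <= j < x.size:  # never crossed: fall back to the boundary
        return float(x[i])
    # linear interpolation between samples i (>= half) and j (< half)
    if y[i] == y[j]:
        return float(x[j])
    t = (y[i] - half) / (y[i] - y[j])
    return float(x[i] + t * (x[j] - x[i]))


def fit_band(
    profile: LineProfile,
    peak_position: float,
    neighbor_peaks: Optional[Sequence[float]] = None,
) -> BandFit:
    """Least-squares Gaussian fit of one band on a background-corrected profile.

    The window half-width is ``min(3 * sigma0, half the distance to the
    nearest neighbouring peak)`` where ``sigma0`` comes from the half-max
    crossings (FWHM / 2.3548). Initial amplitude and centre are the peak
    sample height and position. A diverged fit is returned with
    ``converged=False``; a window of fewer than 5 samples raises
    :class:`BandWindowError`.
    """
    x = profile.positions
    y = profile.intensities
    peak_idx = int(np.argmin(np.abs(x - peak_position)))
    height = float(y[peak_idx])
    left = _half_max_crossing(x, y, peak_idx, height / 2.0, -1)
    right = _half_max_crossing(x, y, peak_idx, height / 2.0, +1)
    fwhm = max(right - left, profile.pixel_size)
    sigma0 = max(fwhm / _FWHM_PER_SIGMA, 0.5 * profile.pixel_size)
    half_width = 3.0 * sigma0
    if neighbor_peaks is not None:
        others = [abs(p - peak_position) for p in neighbor_peaks if p != peak_position]
        if others:
            half_width = min(half_width, 0.5 * min(others))
    mask = np.abs(x - peak_position) <= half_width
    n_window = int(np.count_nonzero(mask))
    if n_window < 5:
        raise BandWindowError(
            f"fit window at {peak_position:.4g} µm has {n_window} samples (< 5)"
        )
    xw, yw = x[mask], y[mask]
    p0 = (height, float(x[peak_idx]), sigma0)
    try:
        popt, _ = curve_fit(_gauss, xw, yw, p0=p0, xtol=1e-8, ftol=1e-8, maxfev=200 * 4)
    except RuntimeError:
        return BandFit(math.nan, math.nan, math.nan, math.nan, False, n_window)
    amplitude, center, sigma = float(popt[0]), float(popt[1]), abs(float(popt[2]))
    if not all(map(math.isfinite, (amplitude, center, sigma))) or sigma == 0.0:
        return BandFit(math.nan, math.nan, math.nan, math.nan, False, n_window)
    resid = yw - _gauss(xw, amplitude, center, sigma)
    rms = float(np.sqrt(np.mean(resid**2)))
    return BandFit(amplitude, center, sigma, rms, True, n_window)


def integrate_band(fit: BandFit) -> float:
    """Analytic area of a converged Gaussian band fit (A * sigma * sqrt(2 pi))."""
    if not fit.converged:
        raise ValueError("cannot integrate a non-converged band fit")
    return fit.area


def smooth_profile(profile: LineProfile, sigma_px: float = 1.0) -> LineProfile:
    """Gaussian smoothing in pixel units with reflect boundaries; 0 is the identity."""
    if sigma_px < 0:
        raise ValueError(f"sigma_px must be >= 0, got {sigma_px}")
    if sigma_px == 0:
        return profile.with_intensities(profile.intensities.copy())
    smoothed = gaussian_filter1d(profile.intensities, sigma_px, mode="reflect")
    return profile.with_intensities(smoothed)
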