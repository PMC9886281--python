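"""Forward models: striated profiles/images, depth stacks, FRAP movies,
control/knockdown image pairs and 1:1 sensorgram series.

All generators are deterministic for a fixed :class:`NoiseSpec` seed, and
for ``model="none"`` their output equals the stated closed forms exactly.
Point bands render as Gaussians of the PSF sigma; block bands render as the
analytic boxcar-Gaussian convolution (difference of error functions), so
ground truth carries no discretisation error. 2-D images are separable: the
1-D profile replicated across rows with independent per-pixel noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.special import erf

from ..kinetics import BliTrace, model_sensorgram
from ..profiles import LineProfile
from .geometry import (
    NO_NOISE,
    AttenuationSpec,
    BliDesign,
    ChannelBands,
    FrapGroundTruth,
    NoiseSpec,
    SarcomereGeometry,
)

__all__ = [
    "make_striated_profile",
    "make_striated_image",
    "make_depth_stack",
    "make_frap_movie",
    "make_degrad_pair",
    "make_bli_sensorgrams",
    "analytic_recovery",
    "FrapLayout",
]

_SQRT2 = math.sqrt(2.0)


def sample_positions(total_length: float, pixel_size: float) -> np.ndarray:
    """Pixel-centre positions: (i + 0.5) * pixel_size covering [0, total_length)."""
    if pixel_size <= 0:
        raise ValueError("pixel_size must be > 0")
    n = int(round(total_length / pixel_size))
    return (np.arange(n) + 0.5) * pixel_size


def _render_channel(x: np.ndarray, geometry: SarcomereGeometry, ch: ChannelBands) -> np.ndarray:
    sigma = geometry.psf_sigma
    L = geometry.sarcomere_length
    y = np.zeros_like(x)
    for j in range(-1, geometry.n_periods + 2):
        z = j * L
        if ch.kind == "point":
            for off in ch.offsets:
                y += ch.amplitude * np.exp(-((x - (z + off)) ** 2) / (2.0 * sigma**2))
        else:
            for start, end in ch.offsets:
                a, b = z + start, z + end
                y += (
                    ch.amplitude
                    * 0.5
                    * (erf((x - a) / (_SQRT2 * sigma)) - erf((x - b) / (_SQRT2 * sigma)))
                )
    return y


def ground_truth_bands(geometry: SarcomereGeometry) -> pd.DataFrame:
    """Every band centre/edge that falls inside the modelled length, per channel."""
    rows = []
    total = geometry.length
    L = geometry.sarcomere_length
    for name in sorted(geometry.channels):
        ch = geometry.channels[name]
        for j in range(-1, geometry.n_periods + 2):
            z = j * L
            if ch.kind == "point":
                for off in ch.offsets:
                    c = z + off
                    if 0.0 <= c < total:
                        rows.append(
                            dict(channel=name, kind="point", center_um=c,
                                 start_um=np.nan, end_um=np.nan, amplitude=ch.amplitude)
                        )
            else:
                for start, end in ch.offsets:
                    c = z + 0.5 * (start + end)
                    if 0.0 <= c < total:
                        rows.append(
                            dict(channel=name, kind="block", center_um=c,
                                 start_um=z + start, end_um=z + end, amplitude=ch.amplitude)
                        )
    df = pd.DataFrame(rows, columns=["channel", "kind", "center_um", "start_um", "end_um", "amplitude"])
    return df.sort_values(["channel", "center_um"], ignore_index=True)


def make_striated_profile(
    geometry: SarcomereGeometry,
    pixel_size: float,
    noise: NoiseSpec = NO_NOISE,
    background: Tuple[float, float] = (0.0, 0.0),
    source_id: str = "synthetic",
) -> tuple[dict[str, LineProfile], pd.DataFrame]:
    """Render one :class:`LineProfile` per channel plus the ground-truth band table.

    ``background`` is ``(slope, offset)`` in a.u./µm and a.u. added to every
    channel. Channels share the position grid; noise is drawn per channel
    in sorted channel order from the noise seed.
    """
    if pixel_size >= geometry.psf_sigma:
        raise ValueError(
            f"pixel_size {pixel_size} must be < psf_sigma {geometry.psf_sigma} "
            "to sample bands adequately"
        )
    x = sample_positions(geometry.length, pixel_size)
    slope, offset = background
    rng = noise.rng()
    profiles: dict[str, LineProfile] = {}
    for name in sorted(geometry.channels):
        clean = _render_channel(x, geometry, geometry.channels[name]) + slope * x + offset
        profiles[name] = LineProfile(
            x, noise.apply(clean, rng), channel=name, pixel_size=pixel_size,
            source_id=source_id,
        )
    return profiles, ground_truth_bands(geometry)


def make_striated_image(
    geometry: SarcomereGeometry,
    pixel_size: float,
    height_px: int = 64,
    noise: NoiseSpec = NO_NOISE,
    background_level: float = 0.0,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Separable 2-D image: the summed-channel profile replicated across rows."""
    x = sample_positions(geometry.length, pixel_size)
    pattern = sum(
        _render_channel(x, geometry, geometry.channels[name])
        for name in sorted(geometry.channels)
    )
    image = np.tile(pattern + background_level, (height_px, 1))
    if rng is None:
        rng = noise.rng()
    return noise.apply(image, rng)


def make_depth_stack(
    geometry: SarcomereGeometry,
    attenuation: AttenuationSpec,
    noise: NoiseSpec = NO_NOISE,
    pixel_size: float = 0.05,
    height_px: int = 64,
) -> tuple[np.ndarray, dict]:
    """Z-stack whose band amplitudes fall off as I0 * exp(-z / decay_length).

    Slice ``k`` equals ``i0 * scale_k`` times the unit-amplitude band
    pattern before noise. Returns the stack and a metadata dict with the
    per-slice depths and scales and the ground-truth band table.
    """
    x = sample_positions(geometry.length, pixel_size)
    pattern = sum(
        _render_channel(x, geometry, geometry.channels[name])
        for name in sorted(geometry.channels)
    )
    scales = np.array([attenuation.scale(k) for k in range(attenuation.n_slices)])
    rng = noise.rng()
    stack = np.empty((attenuation.n_slices, height_px, x.size))
    for k in range(attenuation.n_slices):
        clean = np.tile(attenuation.i0 * scales[k] * pattern, (height_px, 1))
        stack[k] = noise.apply(clean, rng)
    meta = {
        "depths_um": attenuation.depths,
        "scales": scales,
        "pixel_size_um": pixel_size,
        "z_step_um": attenuation.z_step,
        "label": attenuation.label,
        "bands": ground_truth_bands(geometry),
    }
    return stack, meta


def analytic_recovery(truth: FrapGroundTruth, t) -> np.ndarray:
    """Expected bleached-ROI signal, normalised to pre-bleach, at time(s) ``t``.

    ``t`` is measured from the first post-bleach frame; negative times
    return the pre-bleach value 1.
    """
    t = np.asarray(t, dtype=float)
    d, f, tau = truth.bleach_depth, truth.immobile_fraction, truth.recovery_tau
    post = (1.0 - d) + d * (1.0 - f) * (1.0 - np.exp(-np.clip(t, 0.0, None) / tau))
    return np.where(t < 0, 1.0, post)


@dataclass(frozen=True)
class FrapLayout:
    """Pixel-space description of a generated FRAP movie."""

    roi_bleached: Tuple[int, int, int, int]
    roi_unbleached: Tuple[int, int, int, int]
    roi_background: Tuple[int, int, int, int]
    bleach_frame_index: int
    frame_interval: float
    pixel_size: float
    times: np.ndarray  # seconds, 0 at first post-bleach frame


def make_frap_movie(
    geometry: SarcomereGeometry,
    truth: FrapGroundTruth,
    noise: NoiseSpec = NO_NOISE,
    pixel_size: float = 0.2,
    margin_um: float = 3.0,
    muscle_width_um: float = 16.0,
    background_level: float = 10.0,
    baseline_fraction: float = 0.2,
    roi_gap_um: float = 2.0,
) -> tuple[np.ndarray, FrapLayout]:
    """Time-lapse of a striated muscle with a rectangular bleach.

    The field is a background-only strip of ``margin_um`` on top of a muscle
    band of ``muscle_width_um``. Fluorescence inside the bleach ROI follows
    the two-pool recovery model; everything else is constant before noise.
    The camera offset ``background_level`` is not bleached.
    """
    x = sample_positions(geometry.length, pixel_size)
    pattern = sum(
        _render_channel(x, geometry, geometry.channels[name])
        for name in sorted(geometry.channels)
    )
    baseline = baseline_fraction * float(np.max(pattern))
    fluor_1d = pattern + baseline

    margin_px = int(round(margin_um / pixel_size))
    muscle_px = int(round(muscle_width_um / pixel_size))
    height = margin_px + muscle_px
    width = x.size
    fluor = np.zeros((height, width))
    fluor[margin_px:, :] = fluor_1d[None, :]

    y0, x0, y1, x1 = truth.bleach_roi
    b = (
        int(round(y0 / pixel_size)),
        int(round(x0 / pixel_size)),
        int(round(y1 / pixel_size)),
        int(round(x1 / pixel_size)),
    )
    if not (margin_px <= b[0] < b[2] <= height and 0 <= b[1] < b[3] <= width):
        raise ValueError("bleach_roi must lie inside the muscle region of the field")
    gap_px = int(round(roi_gap_um / pixel_size))
    roi_w = b[3] - b[1]
    u = (b[0], b[3] + gap_px, b[2], b[3] + gap_px + roi_w)
    if u[3] > width:
        raise ValueError("field too narrow to place the unbleached ROI; widen geometry")
    bg = (1, b[1], max(2, margin_px - 1), b[3])

    times = (np.arange(truth.n_frames) - truth.n_prebleach) * truth.frame_interval
    factors = analytic_recovery(truth, times)
    rng = noise.rng()
    movie = np.empty((truth.n_frames, height, width))
    mask = np.zeros((height, width), dtype=bool)
    mask[b[0]:b[2], b[1]:b[3]] = True
    for k in range(truth.n_frames):
        frame = background_level + fluor * np.where(mask, factors[k], 1.0)
        movie[k] = noise.apply(frame, rng)
    layout = FrapLayout(b, u, bg, truth.n_prebleach, truth.frame_interval, pixel_size, times)
    return movie, layout


def make_degrad_pair(
    geometry: SarcomereGeometry,
    reduction_factor: float,
    noise: NoiseSpec = NO_NOISE,
    pixel_size: float = 0.1,
    margin_um: float = 2.0,
    muscle_width_um: float = 5.0,
    background_level: float = 20.0,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Control/knockdown image pair with band amplitude scaled by (1 - reduction).

    Both images share the background level and layout; only the fluorescent
    band pattern is scaled. With noise "none" and reduction 0 the images
    are identical.
    """
    if not 0.0 <= reduction_factor <= 1.0:
        raise ValueError("reduction_factor must be in [0, 1]")
    x = sample_positions(geometry.length, pixel_size)
    pattern = sum(
        _render_channel(x, geometry, geometry.channels[name])
        for name in sorted(geometry.channels)
    )
    margin_px = int(round(margin_um / pixel_size))
    muscle_px = int(round(muscle_width_um / pixel_size))
    height = margin_px + muscle_px

    def build(scale: float, rng: np.random.Generator) -> np.ndarray:
        img = np.full((height, x.size), float(background_level))
        img[margin_px:, :] += scale * pattern[None, :]
        return noise.apply(img, rng)

    rng = noise.rng()
    control = build(1.0, rng)
    treated = build(1.0 - reduction_factor, rng)
    band_centers_px = (
        ground_truth_bands(geometry)["center_um"].to_numpy() / pixel_size - 0.5
    )
    truth = {
        "reduction_factor": reduction_factor,
        "background_level": background_level,
        "pixel_size_um": pixel_size,
        "margin_px": margin_px,
        "muscle_rows": (margin_px, height),
        "band_centers_px": band_centers_px,
        "bands": ground_truth_bands(geometry),
    }
    return control, treated, truth


def make_bli_sensorgrams(
    design: BliDesign, noise: NoiseSpec = NO_NOISE
) -> list[BliTrace]:
    """One sensorgram per concentration plus a zero-concentration reference.

    Association follows R(t) = Req (1 - exp(-(kon C + koff) t)) with
    Req = Rmax C / (C + KD); dissociation decays from the association
    endpoint at rate koff. The reference trace (C = 0) is identically zero
    before noise and is returned last.
    """
    t = np.arange(0.0, design.t_assoc + design.t_dissoc + design.sample_interval / 2,
                  design.sample_interval)
    rng = noise.rng()
    traces = []
    for conc in list(design.concentrations) + [0.0]:
        clean = model_sensorgram(design.kon, design.koff, design.rmax, conc, t, design.t_assoc)
        traces.append(
            BliTrace(
                time=t.copy(),
                signal=noise.apply(clean, rng),
                concentration=conc,
                t_assoc=design.t_assoc,
                reference_subtracted=False,
            )
        )
    return traces
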