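"""Parameter objects (with validation) for the synthetic forward models."""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "ChannelBands",
    "SarcomereGeometry",
    "NoiseSpec",
    "AttenuationSpec",
    "FrapGroundTruth",
    "BliDesign",
]


@dataclass(frozen=True)
class ChannelBands:
    """Band layout of one channel within a single sarcomere period.

    ``kind`` is ``"point"`` (each offset is a Gaussian band centre, µm from
    the Z-disc) or ``"block"`` (each offset is a ``(start, end)`` boxcar,
    µm from the Z-disc, rendered as boxcar convolved with the Gaussian PSF).
    """

    kind: str
    offsets: tuple
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("point", "block"):
            raise ValueError(f"unknown band kind {self.kind!r}")
        if self.amplitude <= 0:
            raise ValueError("amplitude must be > 0")
        if self.kind == "block":
            offs = []
            for pair in self.offsets:
                start, end = float(pair[0]), float(pair[1])
                if not start < end:
                    raise ValueError(f"block start must be < end, got ({start}, {end})")
                offs.append((start, end))
            object.__setattr__(self, "offsets", tuple(offs))
        else:
            object.__setattr__(self, "offsets", tuple(float(o) for o in self.offsets))


@dataclass(frozen=True)
class SarcomereGeometry:
    """Periodic two-channel band model of a myofibril.

    Offsets are taken relative to the Z-disc at position 0 of each period
    and are normalised modulo ``sarcomere_length`` into [0, L).
    """

    sarcomere_length: float
    channels: Mapping[str, ChannelBands]
    psf_sigma: float
    n_periods: int = 1

    def __post_init__(self) -> None:
        if self.sarcomere_length <= 0:
            raise ValueError("sarcomere_length must be > 0")
        if self.psf_sigma <= 0:
            raise ValueError("psf_sigma must be > 0")
        if self.n_periods < 1:
            raise ValueError("n_periods must be >= 1")
        if not self.channels:
            raise ValueError("channel map must not be empty")
        L = self.sarcomere_length
        normed = {}
        for name, ch in self.channels.items():
            if ch.kind == "point":
                offs = tuple(float(o) % L for o in ch.offsets)
            else:
                offs = ch.offsets
                for start, end in offs:
                    if end - start >= L:
                        raise ValueError("block longer than one period")
            normed[name] = ChannelBands(ch.kind, offs, ch.amplitude)
        object.__setattr__(self, "channels", normed)

    @property
    def length(self) -> float:
        """Total modelled length in µm."""
        return self.sarcomere_length * self.n_periods


@dataclass(frozen=True)
class NoiseSpec:
    """Pixel-noise model: ``none``, additive ``gaussian``, or ``poisson-gaussian``.

    ``gaussian_sd`` is in absolute intensity units; ``gain`` converts
    intensity to expected photon counts for the Poisson component. The same
    seed and parameters always reproduce identical output.
    """

    model: str = "none"
    gaussian_sd: float = 0.0
    gain: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model not in ("none", "gaussian", "poisson-gaussian"):
            raise ValueError(f"unknown noise model {self.model!r}")
        if self.gaussian_sd < 0:
            raise ValueError("gaussian_sd must be >= 0")
        if self.model == "poisson-gaussian" and self.gain <= 0:
            raise ValueError("gain must be > 0 for poisson-gaussian noise")

    def apply(self, values: np.ndarray, rng: Optional[np.random.Generator] = None) -> np.ndarray:
        """Return a noisy copy of ``values`` (float64)."""
        values = np.asarray(values, dtype=float)
        if self.model == "none":
            return values.copy()
        if rng is None:
            rng = np.random.default_rng(self.seed)
        if self.model == "gaussian":
            return values + rng.normal(0.0, self.gaussian_sd, size=values.shape)
        counts = rng.poisson(np.clip(values * self.gain, 0.0, None))
        out = counts / self.gain
        if self.gaussian_sd > 0:
            out = out + rng.normal(0.0, self.gaussian_sd, size=values.shape)
        return out

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


NO_NOISE = NoiseSpec()


@dataclass(frozen=True)
class AttenuationSpec:
    """Depth attenuation I(z) = I0 * exp(-z / decay_length).

    ``decay_length`` may be ``math.inf`` to disable attenuation.
    """

    decay_length: float
    i0: float = 1.0
    z_step: float = 1.0
    n_slices: int = 10
    label: str = ""

    def __post_init__(self) -> None:
        if not self.decay_length > 0:
            raise ValueError("decay_length must be > 0")
        if self.i0 <= 0:
            raise ValueError("I0 must be > 0")
        if self.z_step <= 0:
            raise ValueError("z_step must be > 0")
        if self.n_slices < 3:
            raise ValueError("n_slices must be >= 3")

    def scale(self, slice_index: int) -> float:
        if math.isinf(self.decay_length):
            return 1.0
        return math.exp(-slice_index * self.z_step / self.decay_length)

    @property
    def depths(self) -> np.ndarray:
        return np.arange(self.n_slices) * self.z_step


@dataclass(frozen=True)
class FrapGroundTruth:
    """Well-mixed two-pool FRAP model (immobile fraction + single-exponential mobile).

    ``bleach_roi`` is ``(y0, x0, y1, x1)`` in µm, half-open. The expected
    normalised signal inside the bleach ROI after bleaching is
    ``(1 - bleach_depth) + bleach_depth * (1 - immobile_fraction) * (1 - exp(-t/tau))``.
    """

    immobile_fraction: float
    recovery_tau: float
    bleach_depth: float
    bleach_roi: Tuple[float, float, float, float]
    frame_interval: float
    n_frames: int
    n_prebleach: int = 3

    def __post_init__(self) -> None:
        if not 0.0 <= self.immobile_fraction <= 1.0:
            raise ValueError("immobile_fraction must be in [0, 1]")
        if self.recovery_tau <= 0:
            raise ValueError("recovery_tau must be > 0")
        if not 0.0 < self.bleach_depth <= 1.0:
            raise ValueError("bleach_depth must be in (0, 1]")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")
        if not 0 < self.n_prebleach < self.n_frames:
            raise ValueError("bleach frame index must lie within the movie")
        y0, x0, y1, x1 = self.bleach_roi
        if not (y0 < y1 and x0 < x1):
            raise ValueError("bleach_roi must have positive extent")


@dataclass(frozen=True)
class BliDesign:
    """Concentration series and phase timing for a 1:1 sensorgram experiment."""

    concentrations: Tuple[float, ...]
    kon: float
    koff: float
    rmax: float = 0.4
    t_assoc: float = 200.0
    t_dissoc: float = 900.0
    sample_interval: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "concentrations", tuple(float(c) for c in self.concentrations)
        )
        if any(c < 0 for c in self.concentrations):
            raise ValueError("concentrations must be >= 0")
        if self.kon <= 0 or self.koff <= 0:
            raise ValueError("kon and koff must be > 0")
        if self.rmax <= 0:
            raise ValueError("rmax must be > 0")
        if self.t_assoc <= 0 or self.t_dissoc <= 0:
            raise ValueError("phase durations must be > 0")
        if self.sample_interval <= 0:
            raise ValueError("sample_interval must be > 0")

    @property
    def kd(self) -> float:
        return self.koff / self.kon
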