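"""Named, versioned scene presets shipped as YAML package data.

Presets make quantitative scenarios reproducible by name: muscle-type band
geometries (``flight``, ``leg``, ``larval``, ``larval_projectin``), the
label-penetration pair (``attenuation_nanobody`` / ``attenuation_antibody``),
the near-immobile FRAP scenario (``stable_sls_frap``), the knockdown pair
(``degrad_larval``) and the high-affinity sensorgram series
(``bli_sls_nano2``).
"""

from __future__ import annotations

import math
from importlib import resources
from typing import Any

import yaml

from .geometry import (
    AttenuationSpec,
    BliDesign,
    ChannelBands,
    FrapGroundTruth,
    SarcomereGeometry,
)

__all__ = [
    "available_presets",
    "load_preset",
    "build_geometry",
    "build_attenuation",
    "build_frap_truth",
    "build_bli_design",
]

_PACKAGE = "sarcoquant.presets"


def available_presets() -> list[str]:
    files = resources.files(_PACKAGE)
    return sorted(p.name[:-5] for p in files.iterdir() if p.name.endswith(".yaml"))


def load_preset(name: str) -> dict[str, Any]:
    path = resources.files(_PACKAGE) / f"{name}.yaml"
    try:
        text = path.read_text()
    except FileNotFoundError:
        raise KeyError(
            f"unknown preset {name!r}; available: {', '.join(available_presets())}"
        ) from None
    return yaml.safe_load(text)


def build_geometry(config: dict[str, Any], n_periods: int | None = None) -> SarcomereGeometry:
    """Build a :class:`SarcomereGeometry` from a preset's ``geometry`` section."""
    geo = config["geometry"] if "geometry" in config else config
    channels = {
        name: ChannelBands(
            kind=spec["kind"],
            offsets=tuple(
                tuple(o) if isinstance(o, (list, tuple)) else o
                for o in spec["offsets_um"]
            ),
            amplitude=float(spec.get("amplitude", 1.0)),
        )
        for name, spec in geo["channels"].items()
    }
    return SarcomereGeometry(
        sarcomere_length=float(geo["sarcomere_length_um"]),
        channels=channels,
        psf_sigma=float(geo["psf_sigma_um"]),
        n_periods=int(n_periods if n_periods is not None else geo.get("n_periods", 1)),
    )


def build_attenuation(config: dict[str, Any]) -> AttenuationSpec:
    att = config["attenuation"]
    decay = att["decay_length_um"]
    return AttenuationSpec(
        decay_length=math.inf if decay in ("inf", None) else float(decay),
        i0=float(att.get("i0", 1.0)),
        z_step=float(att.get("z_step_um", 1.0)),
        n_slices=int(att.get("n_slices", 10)),
        label=str(att.get("label", "")),
    )


def build_frap_truth(config: dict[str, Any]) -> FrapGroundTruth:
    fr = config["frap"]
    return FrapGroundTruth(
        immobile_fraction=float(fr["immobile_fraction"]),
        recovery_tau=float(fr["recovery_tau_s"]),
        bleach_depth=float(fr["bleach_depth"]),
        bleach_roi=tuple(float(v) for v in fr["bleach_roi_um"]),
        frame_interval=float(fr["frame_interval_s"]),
        n_frames=int(fr["n_frames"]),
        n_prebleach=int(fr.get("n_prebleach", 3)),
    )


def build_bli_design(config: dict[str, Any]) -> BliDesign:
    bli = config["bli"]
    return BliDesign(
        concentrations=tuple(float(c) for c in bli["concentrations_M"]),
        kon=float(bli["kon_per_M_s"]),
        koff=float(bli["koff_per_s"]),
        rmax=float(bli.get("rmax_nm", 0.4)),
        t_assoc=float(bli.get("t_assoc_s", 200.0)),
        t_dissoc=float(bli.get("t_dissoc_s", 900.0)),
        sample_interval=float(bli.get("sample_interval_s", 1.0)),
    )
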