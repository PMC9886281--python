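"""Readers and writers for the formats the pipeline touches.

Images travel as multi-page grayscale float32 TIFF with a JSON sidecar
(``<stem>.json``) carrying physical metadata (pixel size, z step, frame
interval). Profiles and sensorgrams are CSV; ROIs, configs and fit results
are JSON/YAML. Image indexing is (slice, row, col), 0-based; physical
positions are (index + 0.5) * pixel_size µm.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any, Optional, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

from .kinetics import BliTrace
from .profiles import BandFit, LineProfile

__all__ = [
    "read_stack",
    "write_stack",
    "read_profiles_csv",
    "write_profiles_csv",
    "write_band_results_csv",
    "read_sensorgrams_csv",
    "write_sensorgrams_csv",
    "read_rois",
    "write_rois",
    "load_config",
    "dump_config",
]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_stack(path, stack: np.ndarray, metadata: Optional[dict] = None) -> None:
    """Write a float32 multi-page grayscale TIFF plus its JSON sidecar."""
    path = Path(path)
    arr = np.asarray(stack, dtype=np.float32)
    if arr.ndim == 2:
        arr = arr[None, ...]
    if arr.ndim != 3:
        raise ValueError(f"expected a 2-D image or 3-D stack, got shape {arr.shape}")
    tifffile.imwrite(path, arr, photometric="minisblack")
    if metadata is not None:
        _sidecar(path).write_text(json.dumps(metadata, indent=2, default=_json_default))


def read_stack(path, pixel_size_um: Optional[float] = None) -> tuple[np.ndarray, dict]:
    """Read a grayscale TIFF stack and its sidecar metadata.

    RGB pages are rejected. A pixel size must come either from the sidecar
    or from the ``pixel_size_um`` argument.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        photometric = tif.pages[0].photometric
        if photometric not in (tifffile.PHOTOMETRIC.MINISBLACK,
                               tifffile.PHOTOMETRIC.MINISWHITE):
            raise ValueError(
                f"{path}: page 0 is {photometric.name}, not grayscale; "
                "RGB/palette TIFFs are unsupported"
            )
        arr = tif.asarray()
    if arr.ndim == 2:
        arr = arr[None, ...]
    if arr.ndim != 3:
        raise ValueError(
            f"{path}: unsupported TIFF layout with shape {arr.shape}; "
            "only grayscale multi-page stacks are readable (RGB is not)"
        )
    meta: dict = {}
    sidecar = _sidecar(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    if pixel_size_um is not None:
        meta["pixel_size_um"] = pixel_size_um
    if "pixel_size_um" not in meta:
        raise ValueError(
            f"{path}: no pixel size in sidecar {sidecar.name}; pass pixel_size_um"
        )
    return arr.astype(np.float32), meta


def write_profiles_csv(path, profiles: Sequence[LineProfile]) -> None:
    frames = [
        pd.DataFrame(
            {
                "position_um": p.positions,
                "intensity": p.intensities,
                "channel": p.channel,
            }
        )
        for p in profiles
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_profiles_csv(path, source_id: str = "") -> dict[str, LineProfile]:
    """Read a profile CSV (position_um, intensity, channel) into per-channel profiles.

    A non-monotone position column is rejected with the offending line
    number (1-based, counting the header).
    """
    path = Path(path)
    df = pd.read_csv(path)
    required = {"position_um", "intensity", "channel"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    out: dict[str, LineProfile] = {}
    for channel, group in df.groupby("channel", sort=True):
        pos = group["position_um"].to_numpy(dtype=float)
        bad = np.flatnonzero(np.diff(pos) <= 0)
        if bad.size:
            line = int(group.index[bad[0] + 1]) + 2  # +1 header, +1 one-based
            raise ValueError(
                f"{path}: line {line}: position_um not strictly increasing "
                f"in channel {channel!r}"
            )
        out[str(channel)] = LineProfile(
            pos, group["intensity"].to_numpy(dtype=float), channel=str(channel),
            source_id=source_id or path.stem,
        )
    return out


def write_band_results_csv(path, rows: Sequence[dict]) -> None:
    """Per-band results with the canonical column order."""
    columns = [
        "source_id", "channel", "center_um", "sigma_um", "amplitude",
        "area", "rms_residual", "converged",
    ]
    pd.DataFrame(list(rows), columns=columns).to_csv(path, index=False)


def band_fit_row(fit: BandFit, source_id: str, channel: str) -> dict:
    return {
        "source_id": source_id,
        "channel": channel,
        "center_um": fit.center,
        "sigma_um": fit.sigma,
        "amplitude": fit.amplitude,
        "area": fit.area if fit.converged else np.nan,
        "rms_residual": fit.rms_residual,
        "converged": fit.converged,
    }


def write_sensorgrams_csv(path, traces: Sequence[BliTrace]) -> None:
    frames = []
    for tr in traces:
        phase = np.where(tr.time <= tr.t_assoc, "association", "dissociation")
        frames.append(
            pd.DataFrame(
                {
                    "time_s": tr.time,
                    "signal_nm": tr.signal,
                    "concentration_M": tr.concentration,
                    "phase": phase,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_sensorgrams_csv(path) -> list[BliTrace]:
    path = Path(path)
    df = pd.read_csv(path)
    required = {"time_s", "signal_nm", "concentration_M", "phase"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    traces = []
    for conc, group in df.groupby("concentration_M", sort=True):
        assoc = group[group["phase"] == "association"]
        t_assoc = float(assoc["time_s"].max()) if len(assoc) else 0.0
        traces.append(
            BliTrace(
                group["time_s"].to_numpy(dtype=float),
                group["signal_nm"].to_numpy(dtype=float),
                float(conc),
                t_assoc,
            )
        )
    return traces


def write_rois(path, rois: Sequence[dict]) -> None:
    for roi in rois:
        _validate_roi(roi)
    Path(path).write_text(json.dumps(list(rois), indent=2, default=_json_default))


def read_rois(path, image_shape: Optional[tuple] = None) -> list[dict]:
    """Load a JSON ROI list, optionally validating bounds against an image shape."""
    path = Path(path)
    rois = json.loads(path.read_text())
    if not isinstance(rois, list):
        raise ValueError(f"{path}: ROI file must contain a JSON list")
    for i, roi in enumerate(rois):
        _validate_roi(roi, f"{path}: ROI {i}")
        if image_shape is not None:
            _check_bounds(roi, image_shape, f"{path}: ROI {i}")
    return rois


def _validate_roi(roi: dict, context: str = "ROI") -> None:
    kind = roi.get("kind")
    if kind == "rect":
        b = roi.get("bounds")
        if not (isinstance(b, (list, tuple)) and len(b) == 4 and b[0] < b[2] and b[1] < b[3]):
            raise ValueError(f"{context}: rect needs bounds [r0, c0, r1, c1] with r0<r1, c0<c1")
    elif kind == "polyline":
        pts = roi.get("points")
        if not (isinstance(pts, (list, tuple)) and len(pts) >= 2):
            raise ValueError(f"{context}: polyline needs >= 2 points")
    else:
        raise ValueError(f"{context}: unknown ROI kind {kind!r}")


def _check_bounds(roi: dict, shape: tuple, context: str) -> None:
    h, w = shape[-2], shape[-1]
    if roi["kind"] == "rect":
        r0, c0, r1, c1 = roi["bounds"]
        if not (0 <= r0 and r1 <= h and 0 <= c0 and c1 <= w):
            raise ValueError(f"{context}: rect {roi['bounds']} outside image {h}x{w}")
    else:
        for r, c in roi["points"]:
            if not (0 <= r < h and 0 <= c < w):
                raise ValueError(f"{context}: point ({r}, {c}) outside image {h}x{w}")


def load_config(path) -> dict[str, Any]:
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        return yaml.safe_load(text)
    return json.loads(text)


def dump_config(path, config: dict[str, Any]) -> None:
    path = Path(path)
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(config, sort_keys=False))
    else:
        path.write_text(json.dumps(config, indent=2, default=_json_default))


def _json_default(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if dataclasses.is_dataclass(obj):
        return dataclasses.asdict(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
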