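"""File I/O and run configuration.

Fixed conventions: CSV is comma-separated, '.' decimal, UTF-8, header
mandatory.  Pixel indices are 0-based, positions sit at pixel centres,
frame 0 is t = 0 h, and all physical quantities are µm / hours.  Stack
geometry (µm/px, dz, depth of field) comes from the sidecar JSON config;
TIFF resolution tags, when present, are checked against it with a warning
on disagreement.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .arbor import ImageStack
from .morphometry import FieldImage
from .tracks import TrackSet

__all__ = [
    "read_tracks",
    "write_tracks",
    "read_stack",
    "write_stack",
    "read_field",
    "write_curve",
    "load_config",
    "write_resolved_config",
]

TRACK_COLUMNS = ["track_id", "frame", "t_hours", "x_um", "y_um"]


def read_tracks(path) -> TrackSet:
    """Read a track table CSV (columns track_id, frame, t_hours, x_um, y_um)."""
    df = pd.read_csv(path)
    missing = [c for c in ("track_id", "t_hours", "x_um", "y_um")
               if c not in df.columns]
    if missing:
        raise ValueError(
            f"{path}: track CSV is missing columns: {', '.join(missing)}"
        )
    return TrackSet.from_frame(df)


def write_tracks(tracks: TrackSet, path) -> None:
    df = tracks.to_frame()[TRACK_COLUMNS]
    df.to_csv(path, index=False, float_format="%.12g")


def read_stack(path, pixel_size: float, dz: float, depth_of_field: float) -> ImageStack:
    """Read a multi-page TIFF z-stack with geometry from the config."""
    try:
        with tifffile.TiffFile(path) as tf:
            data = tf.asarray()
            res = tf.pages[0].tags.get("XResolution")
    except Exception as exc:  # pragma: no cover - corrupt input path
        raise ValueError(f"unreadable TIFF: {path}: {exc}") from exc
    if data.ndim == 2:
        data = data[None, ...]
    if res is not None and res.value[0] not in (0, 1):
        px_from_tag = res.value[1] / res.value[0]  # µm/px if tagged in µm
        if not np.isclose(px_from_tag, pixel_size, rtol=0.05):
            warnings.warn(
                f"{path}: TIFF resolution tag implies {px_from_tag:.4g} µm/px "
                f"but config states {pixel_size:.4g} µm/px; using the config"
            )
    return ImageStack(slices=data.astype(float), pixel_size=pixel_size, dz=dz,
                      depth_of_field=depth_of_field)


def write_stack(stack: ImageStack, path) -> None:
    tifffile.imwrite(path, stack.slices.astype(np.float32))


def read_field(path, pixel_size: float) -> FieldImage:
    try:
        data = tifffile.imread(path)
    except Exception as exc:  # pragma: no cover
        raise ValueError(f"unreadable TIFF: {path}: {exc}") from exc
    if data.ndim != 2:
        raise ValueError(f"{path}: expected a single-plane 2D image")
    return FieldImage(image=data.astype(float), pixel_size=pixel_size)


def write_curve(curve, path) -> None:
    """Write a LagCurve/SpeedCurve/LengthDistribution as CSV."""
    curve.to_frame().to_csv(path, index=False, float_format="%.9g")


def load_config(path, allowed_keys=None, defaults=None) -> dict:
    """Load a JSON run config, rejecting unknown keys."""
    with open(path, encoding="utf-8") as fh:
        cfg = json.load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a JSON object")
    if allowed_keys is not None:
        unknown = sorted(set(cfg) - set(allowed_keys))
        if unknown:
            raise ValueError(f"{path}: unknown config keys: {', '.join(unknown)}")
    merged = dict(defaults or {})
    merged.update(cfg)
    return merged


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def write_resolved_config(cfg: dict, out_dir, name="resolved_config.json") -> Path:
    """Write the resolved configuration next to the outputs.

    The provenance block carries the config hash and package version;
    wall-clock information goes to the log stream only, so output files
    are byte-identical across reruns with the same seed and config.
    """
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    payload = {
        "config": cfg,
        "provenance": {"config_hash": config_hash(cfg), "version": __version__},
    }
    path = out_dir / name
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    return path
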