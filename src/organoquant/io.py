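"""Image/config I/O: canonical (T, Z, C, Y, X) stacks and strict run configs.

TIFF stacks are read and written through tifffile; whatever axis subset the
file carries (a plain 2-D plane, a C-Y-X multichannel image, a full movie)
is normalised to the five-axis order with singleton axes inserted, so every
downstream operation sees the same layout.  Run configuration is a single
YAML file validated strictly — unknown keys are rejected to prevent silent
typos.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import tifffile
import yaml

__all__ = ["ImageStack", "read_stack", "write_stack", "RunConfig", "write_sidecar"]

AXES = "TZCYX"


@dataclass(frozen=True)
class ImageStack:
    """Dense (T, Z, C, Y, X) image with pixel-size metadata."""

    data: np.ndarray
    pixel_size: float | None = None  # um/px
    z_step: float | None = None  # um
    frame_interval_min: float | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.data.ndim != 5:
            raise ValueError(f"ImageStack data must be 5-D (T,Z,C,Y,X), got {self.data.shape}")

    @property
    def shape(self):
        return self.data.shape


def read_stack(path, layout: str | None = None, **meta) -> ImageStack:
    """Read a TIFF into canonical (T, Z, C, Y, X) order.

    ``layout`` names the on-disk axes, e.g. "YX", "CYX", "TZCYX"; missing
    axes become singletons.  Defaults to the trailing axes of TZCYX matching
    the array rank.  A rank/layout mismatch is rejected naming both shapes.
    """
    path = Path(path)
    try:
        arr = tifffile.imread(path)
    except Exception as exc:  # noqa: BLE001 - surface a clean message
        raise IOError(f"cannot read TIFF {path}: {exc}") from exc
    if layout is None:
        layout = AXES[-arr.ndim:]
    layout = layout.upper()
    if len(layout) != arr.ndim:
        raise ValueError(
            f"layout {layout!r} names {len(layout)} axes but {path.name} has "
            f"shape {arr.shape} ({arr.ndim} axes)"
        )
    if sorted(layout) != sorted(set(layout)) or any(ax not in AXES for ax in layout):
        raise ValueError(f"layout {layout!r} must be distinct axes from {AXES!r}")
    # reorder present axes into TZCYX order, then insert singletons
    order = [layout.index(ax) for ax in AXES if ax in layout]
    arr = np.transpose(arr, order)
    for i, ax in enumerate(AXES):
        if ax not in layout:
            arr = np.expand_dims(arr, i)
    return ImageStack(data=arr, **meta)


def write_stack(path, data: np.ndarray, dtype=np.uint16) -> None:
    """Write a (T, Z, C, Y, X) array as a 16-bit multi-page TIFF."""
    arr = np.asarray(data)
    if arr.ndim != 5:
        raise ValueError(f"expected 5-D (T,Z,C,Y,X) data, got shape {arr.shape}")
    if not np.issubdtype(arr.dtype, np.integer):
        info = np.iinfo(dtype)
        arr = np.clip(np.rint(arr), info.min, info.max)
    tifffile.imwrite(Path(path), arr.astype(dtype), metadata={"axes": AXES})


@dataclass
class RunConfig:
    """Pipeline run configuration (single YAML file, strict keys)."""

    input: str = ""
    output_dir: str = "out"
    channels: dict = field(default_factory=lambda: {"nuclear_dye": 0, "reporter": 1})
    pixel_size: float = 0.5  # um/px
    z_step: float = 5.0  # um
    frame_interval_min: float = 10.0
    seed: int = 0
    segmentation: dict = field(default_factory=dict)
    ktr: dict = field(default_factory=dict)
    morphometrics: dict = field(default_factory=dict)
    synthetic: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.frame_interval_min <= 0:
            raise ValueError("frame_interval_min must be positive")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"config {path} must be a mapping")
        known = {f.name for f in fields(cls)}
        unknown = sorted(set(raw) - known)
        if unknown:
            raise ValueError(
                f"unknown config keys {unknown} in {path}; known keys: {sorted(known)}"
            )
        return cls(**raw)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    def require_channel(self, name: str) -> int:
        if name not in self.channels:
            raise KeyError(
                f"channel {name!r} not in channel map; available: {sorted(self.channels)}"
            )
        return int(self.channels[name])


def write_sidecar(csv_path, config: dict, seed: int | None = None) -> Path:
    """Write the provenance JSON next to an output CSV.

    Records package version, a config hash and the seed so that any output
    table can be traced back to the exact run that produced it.
    """
    from . import __version__

    payload = {
        "package": "organoquant",
        "version": __version__,
        "seed": seed,
        "config": config,
        "config_sha256": hashlib.sha256(
            json.dumps(config, sort_keys=True, default=str).encode()
        ).hexdigest(),
    }
    out = Path(str(csv_path) + ".json")
    out.write_text(json.dumps(payload, indent=2, default=str) + "\n")
    return out
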