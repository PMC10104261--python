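"""Image container and TIFF / sidecar I/O.

An :class:`ImageStack` is a plain numpy array (T×Y×X, C×Y×X or Y×X) tagged
with the physical metadata the analysis needs: pixel size (µm/px), frame
interval (s), a channel tag and optional camera constants.  Stacks are
written as multi-page uint16 TIFF with a YAML sidecar carrying the
metadata, so round-trips preserve calibration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import tifffile
import yaml

__all__ = ["ImageStack", "write_stack", "read_stack"]


@dataclass
class ImageStack:
    data: np.ndarray                    # (Y,X), (T,Y,X) or (C,Y,X)
    pixel_size: float                   # µm per pixel
    frame_interval: float = 0.0         # s between frames (0 for snapshots)
    channel: str = ""
    camera: dict[str, float] = field(default_factory=dict)
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    @property
    def n_frames(self) -> int:
        return 1 if self.data.ndim == 2 else self.data.shape[0]

    def frame(self, i: int) -> np.ndarray:
        return self.data if self.data.ndim == 2 else self.data[i]


def write_stack(path: str | Path, stack: ImageStack) -> None:
    """Write a stack as multi-page uint16 TIFF plus a ``.yaml`` sidecar."""
    path = Path(path)
    data = np.clip(np.rint(stack.data), 0, np.iinfo(np.uint16).max).astype(np.uint16)
    tifffile.imwrite(path, data)
    sidecar = {
        "pixel_size_um": float(stack.pixel_size),
        "frame_interval_s": float(stack.frame_interval),
        "channel": stack.channel,
        "camera": {k: float(v) for k, v in stack.camera.items()},
        "meta": _plain(stack.meta),
    }
    path.with_suffix(path.suffix + ".yaml").write_text(
        yaml.safe_dump(sidecar, sort_keys=False)
    )


def read_stack(path: str | Path) -> ImageStack:
    path = Path(path)
    data = tifffile.imread(path)
    sidecar_path = path.with_suffix(path.suffix + ".yaml")
    meta: dict[str, Any] = {}
    if sidecar_path.exists():
        meta = yaml.safe_load(sidecar_path.read_text()) or {}
    return ImageStack(
        data=data,
        pixel_size=float(meta.get("pixel_size_um", 1.0)),
        frame_interval=float(meta.get("frame_interval_s", 0.0)),
        channel=meta.get("channel", ""),
        camera=meta.get("camera", {}) or {},
        meta=meta.get("meta", {}) or {},
    )


def _plain(obj: Any) -> Any:
    """Recursively coerce numpy scalars/arrays into YAML-safe types."""
    if isinstance(obj, dict):
        return {str(k): _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, np.generic):
        return obj.item()
    return obj
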