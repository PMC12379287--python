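"""TIFF + JSON-sidecar persistence for stacks, volumes and reconstructions.

An acquisition is stored as a multi-page TIFF of frames plus a ``.json``
sidecar carrying the schedule, voltages, position, seed and motion flags;
volumes as 3-D TIFF plus spacing/landmark metadata. Tables go through CSV.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Optional, Tuple

import numpy as np
import tifffile

from .assemble import Volume
from .config import AcquisitionConfig
from .simulate import FrameStack

__all__ = ["save_stack", "load_stack", "save_volume", "load_volume"]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def save_stack(path, stack: FrameStack) -> None:
    """Write frames as multi-page TIFF with a JSON sidecar of metadata."""
    path = Path(path)
    tifffile.imwrite(path, stack.frames.astype(np.float32), photometric="minisblack")
    meta = {
        "config": dataclasses.asdict(stack.config),
        "voltages": stack.voltages.tolist(),
        "motion_flags": stack.motion_flags.tolist(),
        "position": list(stack.position) if stack.position is not None else None,
        "station": stack.station,
        "seed": stack.truth.seed if stack.truth is not None else None,
    }
    _sidecar(path).write_text(json.dumps(meta, indent=1))


def load_stack(path) -> FrameStack:
    path = Path(path)
    frames = tifffile.imread(path).astype(float)
    meta = json.loads(_sidecar(path).read_text())
    return FrameStack(
        frames=frames,
        voltages=np.asarray(meta["voltages"]),
        config=AcquisitionConfig(**meta["config"]),
        motion_flags=np.asarray(meta["motion_flags"], dtype=bool),
        position=tuple(meta["position"]) if meta["position"] else None,
        station=meta.get("station"),
    )


def save_volume(path, volume: Volume, landmark: Optional[str] = None) -> None:
    """Write BURST*, B-mode, mask and exclusion map as one 4-page-axis TIFF."""
    path = Path(path)
    arr = np.stack([
        volume.burst_star, volume.bmode,
        volume.mask.astype(float), volume.exclusion_map.astype(float),
    ]).astype(np.float32)
    tifffile.imwrite(path, arr, photometric="minisblack")
    meta = {
        "channels": ["burst_star", "bmode", "mask", "exclusion_map"],
        "voxel_spacing_mm": list(volume.voxel_spacing),
        "landmark": landmark,
    }
    _sidecar(path).write_text(json.dumps(meta, indent=1))


def load_volume(path) -> Tuple[Volume, dict]:
    path = Path(path)
    arr = tifffile.imread(path).astype(float)
    meta = json.loads(_sidecar(path).read_text())
    vol = Volume(
        burst_star=arr[0], bmode=arr[1],
        voxel_spacing=tuple(meta["voxel_spacing_mm"]),
        mask=arr[2] > 0.5, exclusion_map=arr[3] > 0.5,
    )
    return vol, meta
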