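"""Stitching per-position reconstructions into planes, volumes and ex vivo series.

In vivo, each transverse plane is the lateral concatenation of the
across-body acquisitions at one longitudinal station; stacking all planes
gives anisotropic 3-D BURST*/B-mode arrays (0.5 mm between planes versus
sub-0.1-mm in-plane pixels — the voxels are not isotropic). BURST* voxels
outside the per-plane GI-tract ROI or belonging to motion-excluded
acquisitions are zeroed; the B-mode channel is kept everywhere for
anatomical context.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .config import ScanPlan
from .reconstruct import ReconImage, bmode, burst_star
from .simulate import FrameStack, ScanSet

__all__ = [
    "ROISet",
    "Volume",
    "ExVivoSeries",
    "stitch_transverse",
    "build_volume",
    "assemble_ex_vivo",
    "rois_from_truth",
]


@dataclass
class ROISet:
    """Per-plane GI-tract masks (boolean, plane pixel coordinates)."""

    masks: Dict[int, np.ndarray]  # longitudinal station -> 2-D bool mask
    background_rois: Dict[int, np.ndarray] = field(default_factory=dict)

    def mask_for(self, station: int, shape: Tuple[int, int], strict: bool = False) -> np.ndarray:
        m = self.masks.get(station)
        if m is None:
            if strict:
                raise KeyError(f"no ROI for plane {station}")
            import warnings

            warnings.warn(f"no ROI for plane {station}; treating plane as background")
            return np.zeros(shape, dtype=bool)
        m = np.asarray(m, dtype=bool)
        if m.shape != shape:
            raise ValueError(f"ROI shape {m.shape} does not match plane {shape}")
        return m


@dataclass
class Volume:
    """Stitched 3-D arrays [longitudinal, axial, lateral] with spacing metadata."""

    burst_star: np.ndarray
    bmode: np.ndarray
    voxel_spacing: Tuple[float, float, float]  # (longitudinal, axial, lateral) mm/voxel
    mask: np.ndarray
    exclusion_map: np.ndarray

    def __post_init__(self) -> None:
        shapes = {a.shape for a in (self.burst_star, self.bmode, self.mask, self.exclusion_map)}
        if len(shapes) != 1:
            raise ValueError("volume arrays must share one shape")
        if any(s <= 0 for s in self.voxel_spacing):
            raise ValueError("voxel spacing must be positive")


@dataclass
class ExVivoSeries:
    """Ordered per-station reconstructions with signed length coordinates.

    Length is measured in mm relative to a named landmark (the cecum);
    positive toward the rectum.
    """

    length_mm: np.ndarray
    burst_star: List[ReconImage]
    bmode: List[ReconImage]
    landmark: str = "cecum"
    step_mm: float = 1.0


def _block_for(img: np.ndarray, step_px: int, policy: str) -> np.ndarray:
    """Reduce one acquisition's lateral extent to the stage step width."""
    w = img.shape[1]
    if step_px == w:
        return img
    if step_px < w:
        if policy == "crop":
            lo = (w - step_px) // 2
            return img[:, lo:lo + step_px]
        if policy == "average":
            # keep full width; overlap averaging handled by caller
            return img
        raise ValueError(f"unknown stitch policy {policy!r}")
    out = np.zeros((img.shape[0], step_px))
    lo = (step_px - w) // 2
    out[:, lo:lo + w] = img  # stage step exceeds image width: zero-filled gap
    return out


def stitch_transverse(
    images: Sequence[ReconImage],
    lateral_step_mm: float,
    lateral_spacing: float,
    policy: str = "crop",
    zero_excluded: bool = True,
) -> np.ndarray:
    """Laterally concatenate ordered across-body images at stage spacing.

    When the stage step differs from the image width the default policy crops
    each block to the step width centered on the beam axis; ``average``
    blends overlapping columns. Excluded images contribute a zero block when
    ``zero_excluded`` (used for the BURST* channel; B-mode passes False).
    """
    if not images:
        raise ValueError("no images to stitch")
    heights = {im.pixels.shape[0] for im in images}
    if len(heights) != 1:
        raise ValueError("images must share axial extent")
    step_px = int(round(lateral_step_mm / lateral_spacing))
    if step_px < 1:
        raise ValueError("stage step smaller than one pixel")

    w = images[0].pixels.shape[1]
    if policy == "average" and step_px < w:
        h = next(iter(heights))
        total = step_px * (len(images) - 1) + w
        acc = np.zeros((h, total))
        cnt = np.zeros((h, total))
        for k, im in enumerate(images):
            px = np.zeros_like(im.pixels) if (im.excluded and zero_excluded) else im.pixels
            acc[:, k * step_px:k * step_px + w] += px
            cnt[:, k * step_px:k * step_px + w] += 1
        return acc / np.maximum(cnt, 1)

    blocks = []
    for im in images:
        px = np.zeros_like(im.pixels) if (im.excluded and zero_excluded) else im.pixels
        blocks.append(_block_for(px, step_px, policy))
    return np.concatenate(blocks, axis=1)


def build_volume(
    scanset: ScanSet,
    rois: ROISet,
    exclusions: Sequence[Tuple[int, int]] = (),
    policy: str = "crop",
    strict_rois: bool = False,
) -> Volume:
    """Reconstruct, stitch and mask a whole stage scan into a Volume.

    BURST* voxels outside the per-plane GI mask or within motion-excluded
    acquisitions are set to zero; the B-mode channel keeps the first
    collapsing frame everywhere. ``exclusions`` lists (lateral, longitudinal)
    positions zeroed for breathing; the exclusion map records those voxels.
    """
    plan = scanset.plan
    cfg = next(iter(scanset.stacks.values())).config
    excl = set(exclusions)

    bs_planes, bm_planes, mask_planes, ex_planes = [], [], [], []
    for j in range(plan.longitudinal_steps):
        row = [scanset.stacks[(i, j)] for i in range(plan.lateral_steps)]
        bs_imgs, bm_imgs, ex_imgs = [], [], []
        for stack in row:
            bsi = burst_star(stack)
            if stack.position in excl:
                bsi.excluded = True
                bsi.exclusion_reason = "breathing"
            bs_imgs.append(bsi)
            bm_imgs.append(bmode(stack))
            ones = ReconImage(np.ones_like(bsi.pixels), kind="bmode", frames_used=0)
            if stack.position in excl:
                ones.excluded = True
                ones.exclusion_reason = "breathing"
            ex_imgs.append(ones)
        bs_plane = stitch_transverse(bs_imgs, plan.lateral_step_mm, cfg.lateral_spacing, policy)
        bm_plane = stitch_transverse(
            bm_imgs, plan.lateral_step_mm, cfg.lateral_spacing, policy, zero_excluded=False
        )
        # excluded blocks show up as zeros in this indicator plane
        ex_plane = stitch_transverse(ex_imgs, plan.lateral_step_mm, cfg.lateral_spacing, policy) == 0

        gi = rois.mask_for(j, bs_plane.shape, strict=strict_rois)
        bs_plane = np.where(gi & ~ex_plane, bs_plane, 0.0)
        bs_planes.append(bs_plane)
        bm_planes.append(bm_plane)
        mask_planes.append(gi)
        ex_planes.append(ex_plane)

    return Volume(
        burst_star=np.stack(bs_planes),
        bmode=np.stack(bm_planes),
        voxel_spacing=(plan.longitudinal_step_mm, cfg.axial_spacing, cfg.lateral_spacing),
        mask=np.stack(mask_planes),
        exclusion_map=np.stack(ex_planes),
    )


def assemble_ex_vivo(
    stacks: Sequence[FrameStack],
    landmark_station: int,
    step_mm: float = 1.0,
    landmark: str = "cecum",
) -> ExVivoSeries:
    """Order per-station GI-length acquisitions into a series with signed
    length coordinates (negative proximal of the landmark, positive toward
    the rectum)."""
    if not stacks:
        raise ValueError("empty ex vivo series")
    stations = [s.station for s in stacks]
    if any(st is None for st in stations):
        raise ValueError("every stack needs a station index")
    if list(stations) != sorted(stations):
        raise ValueError("stacks must be ordered by station")
    length = (np.asarray(stations, dtype=float) - landmark_station) * step_mm
    return ExVivoSeries(
        length_mm=length,
        burst_star=[burst_star(s) for s in stacks],
        bmode=[bmode(s) for s in stacks],
        landmark=landmark,
        step_mm=step_mm,
    )


def rois_from_truth(scanset: ScanSet, dilate: int = 2) -> ROISet:
    """Build per-plane GI masks from simulator ground truth (test helper:
    the mask is the dilated support of the true gas-vesicle map)."""
    from scipy import ndimage

    plan = scanset.plan
    cfg = next(iter(scanset.stacks.values())).config
    step_px = int(round(plan.lateral_step_mm / cfg.lateral_spacing))
    masks = {}
    for j in range(plan.longitudinal_steps):
        blocks = []
        for i in range(plan.lateral_steps):
            stack = scanset.stacks[(i, j)]
            if stack.truth is None:
                raise ValueError("stacks carry no truth")
            blocks.append(_block_for(stack.truth.gv_map > 0, step_px, "crop"))
        plane = np.concatenate(blocks, axis=1)
        if dilate:
            plane = ndimage.binary_dilation(plane, iterations=dilate)
        masks[j] = plane
    return ROISet(masks=masks)
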