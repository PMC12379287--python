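"""SBR, dB conversion, comparative display normalization, depth integration,
total signal and ex vivo length profiles.

Signal-to-background ratio (SBR) is the mean sample-ROI intensity divided by
the mean background-ROI intensity; decibel conversion is 20*log10(SBR).
For side-by-side display, every image in a compared set is divided by the
set-wide average background, and one pair of colormap limits is shared by
the whole set: lower limit = the constant A, upper limit = B times the
set-wide maximum over the average background. Images are then converted to
dB with values below the lower limit floored to it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .assemble import ExVivoSeries, Volume
from .config import DisplayParams

__all__ = [
    "QuantResult",
    "sbr",
    "to_db",
    "normalize_display",
    "integrate_2d",
    "overlay",
    "total_signal",
    "ex_vivo_profile",
]


@dataclass
class QuantResult:
    """Scalar quantification outputs for one sample or volume."""

    sbr: Optional[float] = None
    sbr_db: Optional[float] = None
    total_signal: Optional[float] = None
    profile: Optional[pd.DataFrame] = None
    flags: List[str] = field(default_factory=list)


def sbr(image: np.ndarray, sample_roi: np.ndarray, background_roi: np.ndarray) -> float:
    """Mean sample-ROI intensity over mean background-ROI intensity."""
    image = np.asarray(image, dtype=float)
    s = np.asarray(sample_roi, dtype=bool)
    b = np.asarray(background_roi, dtype=bool)
    if not s.any() or not b.any():
        raise ValueError("ROIs must be nonempty")
    bg = image[b].mean()
    if bg <= 0:
        raise ValueError("background mean must be positive for SBR")
    return float(image[s].mean() / bg)


def to_db(x) -> np.ndarray | float:
    """20*log10(x); defined only for positive x."""
    arr = np.asarray(x, dtype=float)
    if np.any(arr <= 0):
        raise ValueError("dB conversion undefined for nonpositive values")
    out = 20.0 * np.log10(arr)
    return float(out) if np.isscalar(x) or arr.ndim == 0 else out


def normalize_display(
    images: Sequence[np.ndarray],
    params: DisplayParams,
    background_rois: Optional[Sequence[np.ndarray]] = None,
) -> Tuple[List[np.ndarray], Tuple[float, float]]:
    """Normalize a compared set of images for shared-colormap display.

    Every image is divided by the set-wide average background (mean over the
    background ROIs, or over whole images when no ROIs are given), the shared
    limits (A, B * max / avg_background) are computed once for the set, and
    images are converted to dB with pixels below the lower limit floored to
    it. Returns (dB images, (lower, upper) limits in dB).
    """
    if not images:
        raise ValueError("empty image set")
    images = [np.asarray(im, dtype=float) for im in images]
    if background_rois is None:
        bg_vals = np.concatenate([im.ravel() for im in images])
    else:
        if len(background_rois) != len(images):
            raise ValueError("one background ROI per image required")
        bg_vals = np.concatenate(
            [im[np.asarray(r, dtype=bool)].ravel() for im, r in zip(images, background_rois)]
        )
    avg_bg = float(bg_vals.mean())
    if avg_bg <= 0:
        raise ValueError("average background must be positive")

    lower_lin = params.A
    upper_lin = params.B * max(float(im.max()) for im in images) / avg_bg
    lower_db = 20.0 * np.log10(lower_lin)
    upper_db = 20.0 * np.log10(upper_lin) if upper_lin > 0 else lower_db

    out = []
    for im in images:
        norm = im / avg_bg
        with np.errstate(divide="ignore", invalid="ignore"):
            db = 20.0 * np.log10(np.where(norm > 0, norm, np.nan))
        db = np.where(np.isnan(db) | (db < lower_db), lower_db, db)
        out.append(db)
    return out, (float(lower_db), float(upper_db))


def _depth_slice(depth_range_mm: Tuple[float, float], axial_spacing: float, n_axial: int) -> slice:
    """Half-open [lo, hi) mm depth window to voxel indices (boundaries rounded down)."""
    lo_mm, hi_mm = depth_range_mm
    lo = int(np.floor(lo_mm / axial_spacing))
    hi = int(np.floor(hi_mm / axial_spacing))
    if lo < 0 or hi > n_axial or lo >= hi:
        raise ValueError(f"depth range {depth_range_mm} mm outside volume")
    return slice(lo, hi)


def integrate_2d(
    volume: Volume, bmode_depth_range: Tuple[float, float] = (4.0, 8.0)
) -> Tuple[np.ndarray, np.ndarray]:
    """Depth-integrated 2-D maps [longitudinal, lateral].

    The B-mode channel is summed over the stated axial window (default
    4-8 mm, the depth of the mouse); the BURST* channel is summed over the
    full depth of the ROI (its voxels are already zero outside the mask).
    """
    ax_spacing = volume.voxel_spacing[1]
    sl = _depth_slice(bmode_depth_range, ax_spacing, volume.bmode.shape[1])
    bmode_2d = volume.bmode[:, sl, :].sum(axis=1)
    burst_2d = volume.burst_star.sum(axis=1)
    return bmode_2d, burst_2d


def overlay(
    burst_2d: np.ndarray,
    bmode_2d: np.ndarray,
    threshold: Optional[float] = None,
    percentile: float = 97.5,
    params: Optional[DisplayParams] = None,
) -> np.ndarray:
    """Hot-over-gray composite: thresholded dB BURST* on dB B-mode.

    BURST* pixels at or below the threshold are transparent. The default
    threshold policy takes the given percentile of the positive BURST*
    distribution as a noise floor; pass ``threshold`` for a fixed value.
    Returns an RGB float array.
    """
    burst_2d = np.asarray(burst_2d, dtype=float)
    bmode_2d = np.asarray(bmode_2d, dtype=float)
    if burst_2d.shape != bmode_2d.shape:
        raise ValueError("overlay inputs must share shape")
    if threshold is None:
        finite = burst_2d[np.isfinite(burst_2d)]
        threshold = float(np.percentile(finite, percentile)) if finite.size else 0.0
    shown = burst_2d > threshold

    from matplotlib import cm

    def _db_scaled(img, mask=None):
        pos = img > 0
        out = np.zeros_like(img)
        if pos.any():
            db = 20.0 * np.log10(img[pos])
            lo, hi = db.min(), db.max()
            out[pos] = (db - lo) / (hi - lo) if hi > lo else 1.0
        return out

    gray = cm.gray(_db_scaled(bmode_2d))[..., :3]
    hot = cm.hot(_db_scaled(np.where(shown, burst_2d, 0.0)))[..., :3]
    comp = gray.copy()
    comp[shown] = hot[shown]
    return comp


def total_signal(volume: Volume, clip_negative: bool = False) -> float:
    """Sum of BURST* voxels inside the ROI, excluding breathing-excluded voxels.

    The sum is signed (negative differencing values included) by default; a
    clip-at-zero variant is available for sensitivity analysis.
    """
    keep = volume.mask & ~volume.exclusion_map
    vals = volume.burst_star[keep]
    if clip_negative:
        vals = np.clip(vals, 0.0, None)
    return float(vals.sum())


def ex_vivo_profile(
    series: ExVivoSeries,
    depth_range_mm: Tuple[float, float] = (4.0, 12.0),
    axial_spacing: Optional[float] = None,
) -> pd.DataFrame:
    """Integrated BURST* signal along the GI length.

    Per station, BURST* pixel intensities are summed over the stated depth
    band (default 4-12 mm) and the full transducer width; keyed by signed
    length in mm relative to the landmark (cecum).
    """
    if series.length_mm is None or len(series.length_mm) == 0:
        raise ValueError("series has no stations")
    rows = []
    for L, im in zip(series.length_mm, series.burst_star):
        if axial_spacing is None:
            raise ValueError("axial_spacing (mm/px) required to place the depth window")
        sl = _depth_slice(depth_range_mm, axial_spacing, im.pixels.shape[0])
        rows.append({"length_mm": float(L), "integrated_signal": float(im.pixels[sl, :].sum())})
    return pd.DataFrame(rows)
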