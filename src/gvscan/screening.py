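"""Replica-plate patch quantification and anchored relative opacity.

Gas-vesicle expression makes colonies optically opaque, so sensor variants
are ranked by how much more opaque their patches are with inducer than
without. Each patch's mean intensity is corrected by subtracting the mean of
an adjacent background ROI (white-trans plate images have nonuniform
background), then normalized so the parent strain at 0 mM inducer / 30 C
maps to 0 and at 1 mM / 30 C maps to 1 ("relative patch opacity").
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "PatchMeasurement",
    "OpacityAnchors",
    "measure_patch",
    "relative_opacity",
    "select_hits",
    "disk_roi",
]


@dataclass
class PatchMeasurement:
    """Background-corrected patch intensity for one strain under one condition."""

    patch_mean: float
    adjacent_background_mean: float
    strain_id: str = ""
    inducer_um: Optional[float] = None
    temperature_c: Optional[float] = None

    @property
    def corrected(self) -> float:
        """Patch mean minus adjacent-background mean (may be negative)."""
        return self.patch_mean - self.adjacent_background_mean


@dataclass(frozen=True)
class OpacityAnchors:
    """Parent-strain corrected opacities anchoring the relative scale."""

    a0: float  # parent at 0 mM inducer, 30 C
    a1: float  # parent at 1 mM inducer, 30 C

    def __post_init__(self) -> None:
        if not self.a1 > self.a0:
            raise ValueError("1 mM anchor must exceed 0 mM anchor")


def disk_roi(shape: Tuple[int, int], center: Tuple[int, int], radius: int) -> np.ndarray:
    """Boolean disk mask (strict interior, matching skimage.draw.disk)."""
    yy, xx = np.ogrid[0:shape[0], 0:shape[1]]
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 < radius ** 2


def measure_patch(
    image: np.ndarray,
    patch_roi: np.ndarray,
    background_roi: np.ndarray,
    strain_id: str = "",
    inducer_um: Optional[float] = None,
    temperature_c: Optional[float] = None,
) -> PatchMeasurement:
    """Mean patch intensity corrected by the adjacent-background mean."""
    image = np.asarray(image, dtype=float)
    p = np.asarray(patch_roi, dtype=bool)
    b = np.asarray(background_roi, dtype=bool)
    if p.shape != image.shape or b.shape != image.shape:
        raise ValueError("ROIs must match the image shape")
    if not p.any() or not b.any():
        raise ValueError("ROIs must be nonempty")
    if (p & b).any():
        raise ValueError("patch and background ROIs must be disjoint")
    return PatchMeasurement(
        patch_mean=float(image[p].mean()),
        adjacent_background_mean=float(image[b].mean()),
        strain_id=strain_id,
        inducer_um=inducer_um,
        temperature_c=temperature_c,
    )


def relative_opacity(m: PatchMeasurement, anchors: OpacityAnchors) -> float:
    """(corrected - a0) / (a1 - a0): 0 = parent uninduced, 1 = parent induced."""
    return (m.corrected - anchors.a0) / (anchors.a1 - anchors.a0)


def select_hits(
    measurements: Dict[str, Dict[float, PatchMeasurement]],
    anchors: OpacityAnchors,
    margin_fraction: float = 0.25,
) -> pd.DataFrame:
    """Rank candidates whose induced opacity clears the uninduced by a margin.

    ``measurements`` maps strain_id -> {0.0: PatchMeasurement at 0 mM,
    1000.0: at 1 mM} (inducer in uM). A candidate is a hit when its 1 mM
    corrected opacity exceeds its 0 mM corrected opacity by
    ``margin_fraction * (a1 - a0)``. Hits are ranked by 1 mM relative
    opacity descending, ties broken by the lower 0 mM value.
    """
    span = anchors.a1 - anchors.a0
    rows = []
    for strain, conds in measurements.items():
        if 0.0 not in conds or 1000.0 not in conds:
            raise ValueError(f"strain {strain!r} missing a 0 or 1 mM condition")
        m0, m1 = conds[0.0], conds[1000.0]
        rel0 = relative_opacity(m0, anchors)
        rel1 = relative_opacity(m1, anchors)
        rows.append({
            "strain_id": strain,
            "corrected_0mM": m0.corrected,
            "corrected_1mM": m1.corrected,
            "relative_opacity_0mM": rel0,
            "relative_opacity_1mM": rel1,
            "is_hit": m1.corrected > m0.corrected + margin_fraction * span,
        })
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    df = df.sort_values(
        ["is_hit", "relative_opacity_1mM", "relative_opacity_0mM"],
        ascending=[False, False, True],
        kind="mergesort",
    ).reset_index(drop=True)
    return df
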