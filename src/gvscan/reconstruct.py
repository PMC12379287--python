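"""Collapse-differencing reconstructions and motion screening.

Three reconstructions of a multi-frame collapse acquisition:

* ``burst_invitro`` — first collapsing frame minus last collapsing frame.
  In vitro the sample is static, so the full collapse (brightest to fully
  collapsed) maximizes gas-vesicle contrast.
* ``burst_star`` — second collapsing frame minus first. In the GI tract the
  vesicle-specific signal rises from the first to the second collapsing
  frame, and using only adjacent frames is robust to tissue motion.
* ``bmode`` — the first collapsing frame unmodified, used as anatomy.

Difference images are signed; negative pixels are retained through
quantification and only handled at display time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple, Union

import numpy as np

from .simulate import FrameStack

__all__ = ["ReconImage", "burst_invitro", "burst_star", "bmode", "screen_motion"]


@dataclass
class ReconImage:
    """One reconstructed 2-D image with frame bookkeeping."""

    pixels: np.ndarray  # linear units; signed for difference images
    kind: str  # burst | burst_star | bmode
    frames_used: Union[int, Tuple[int, int]]  # collapsing-frame ordinals
    excluded: bool = False
    exclusion_reason: Optional[str] = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.excluded and not self.exclusion_reason:
            raise ValueError("excluded images must carry a reason")


def _require_collapsing(stack: FrameStack, n: int) -> np.ndarray:
    frames = stack.collapsing_frames
    if frames.shape[0] < n:
        raise ValueError(f"need at least {n} collapsing frames, have {frames.shape[0]}")
    return frames


def burst_invitro(stack: FrameStack) -> ReconImage:
    """BURST image: first collapsing frame minus last collapsing frame (signed)."""
    frames = _require_collapsing(stack, 2)
    return ReconImage(
        pixels=frames[0] - frames[-1],
        kind="burst",
        frames_used=(0, frames.shape[0] - 1),
    )


def burst_star(stack: FrameStack) -> ReconImage:
    """BURST* image: second collapsing frame minus the first (signed)."""
    frames = _require_collapsing(stack, 2)
    return ReconImage(pixels=frames[1] - frames[0], kind="burst_star", frames_used=(1, 0))


def bmode(stack: FrameStack) -> ReconImage:
    """B-mode anatomy image: the first collapsing frame, unmodified."""
    frames = _require_collapsing(stack, 1)
    return ReconImage(pixels=frames[0].copy(), kind="bmode", frames_used=0)


def screen_motion(
    stack: FrameStack,
    decorrelation_threshold: float = 0.5,
    mode: str = "burst_star",
    background_band: Optional[Tuple[slice, slice]] = None,
    manual_exclusions: Sequence = (),
) -> Tuple[bool, float]:
    """Score inter-frame decorrelation between the two frames the active
    reconstruction differences, and decide exclusion.

    Score is ``1 - Pearson correlation`` computed over ``background_band``
    (default: the whole image). Returns ``(excluded, score)``; an acquisition
    is excluded when the score exceeds the threshold or its position/station
    is on the ``manual_exclusions`` list (the manual list is authoritative,
    mirroring by-eye exclusion of acquisitions during which breathing
    occurred).
    """
    frames = _require_collapsing(stack, 2)
    if mode == "burst_star":
        a, b = frames[1], frames[0]
    elif mode == "burst":
        a, b = frames[0], frames[-1]
    else:
        raise ValueError(f"unknown reconstruction mode {mode!r}")
    if background_band is not None:
        a, b = a[background_band], b[background_band]
    a = a.ravel()
    b = b.ravel()
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        warnings.warn("constant frames: correlation undefined, motion score set to 0")
        score = 0.0
    else:
        score = float(1.0 - np.corrcoef(a, b)[0, 1])
    manual = (stack.position in manual_exclusions) or (stack.station in manual_exclusions)
    return (score > decorrelation_threshold) or manual, score
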