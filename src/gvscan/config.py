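"""Acquisition schedules, scan plans and display constants.

The four named acquisition schedules encode the voltage sequences used for
collapse-based (BURST) imaging with the two high-frequency linear arrays
(L22-14v and L22-14vX): a run of low-voltage frames in which gas vesicles
scatter weakly but are not destroyed, followed by a run of frames at the
collapsing voltage during which the vesicle-specific signal transiently
spikes and then disappears as the vesicles collapse irreversibly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Tuple

__all__ = [
    "AcquisitionConfig",
    "ScanPlan",
    "DisplayParams",
    "build_schedule",
    "plan_in_vivo_scan",
    "transmit_event_count",
    "display_constants",
    "SCHEDULES",
    "DISPLAY_CONSTANTS",
]


@dataclass(frozen=True)
class AcquisitionConfig:
    """One position's multi-frame acquisition schedule and image geometry.

    Voltages are transducer drive voltages in volts; ``high_voltage`` is the
    collapsing voltage. ``axial_spacing``/``lateral_spacing`` are mm per pixel
    of the beamformed envelope image.
    """

    transducer_id: str
    mode: str  # burst_invitro | burst_star_invivo | burst_star_exvivo
    n_low_frames: int
    n_high_frames: int
    low_voltage: float
    high_voltage: float
    frequency_mhz: float = 18.0
    focus_depth_mm: float = 6.0
    n_half_cycles: int = 3
    accumulations: int = 1
    beams_per_transmit: int = 1
    axial_spacing: float = 0.1
    lateral_spacing: float = 0.1

    def __post_init__(self) -> None:
        if self.transducer_id not in ("L22-14v", "L22-14vX"):
            raise ValueError(f"unknown transducer {self.transducer_id!r}")
        if self.mode not in ("burst_invitro", "burst_star_invivo", "burst_star_exvivo"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.n_low_frames < 1:
            raise ValueError("need at least one low-voltage frame")
        if self.n_high_frames < 2:
            raise ValueError("collapse differencing needs at least two collapsing frames")
        if not self.high_voltage > self.low_voltage:
            raise ValueError("collapsing voltage must exceed the low voltage")
        if self.axial_spacing <= 0 or self.lateral_spacing <= 0:
            raise ValueError("pixel spacings must be positive")

    @property
    def n_frames(self) -> int:
        return self.n_low_frames + self.n_high_frames

    @property
    def voltages(self) -> Tuple[float, ...]:
        return (self.low_voltage,) * self.n_low_frames + (self.high_voltage,) * self.n_high_frames

    @property
    def collapsing_indices(self) -> Tuple[int, ...]:
        """Frame indices acquired at the collapsing voltage."""
        return tuple(range(self.n_low_frames, self.n_frames))


# The four named schedules. In vitro runs average 50 accumulations per frame;
# in vivo/ex vivo runs multiplex three 32-aperture focused beams per transmit.
SCHEDULES = {
    "L22-14v in vitro": AcquisitionConfig(
        transducer_id="L22-14v", mode="burst_invitro",
        n_low_frames=10, n_high_frames=46, low_voltage=1.6, high_voltage=25.0,
        frequency_mhz=18.0, focus_depth_mm=6.0, n_half_cycles=3,
        accumulations=50, beams_per_transmit=1,
    ),
    "L22-14vX in vitro": AcquisitionConfig(
        transducer_id="L22-14vX", mode="burst_invitro",
        n_low_frames=1, n_high_frames=7, low_voltage=1.6, high_voltage=20.0,
        frequency_mhz=18.0, focus_depth_mm=6.0, n_half_cycles=3,
        accumulations=50, beams_per_transmit=3,
    ),
    "L22-14v in vivo": AcquisitionConfig(
        transducer_id="L22-14v", mode="burst_star_invivo",
        n_low_frames=1, n_high_frames=7, low_voltage=1.6, high_voltage=25.0,
        frequency_mhz=18.0, focus_depth_mm=6.0, n_half_cycles=6,
        accumulations=1, beams_per_transmit=3,
    ),
    "L22-14vX in vivo": AcquisitionConfig(
        transducer_id="L22-14vX", mode="burst_star_invivo",
        n_low_frames=1, n_high_frames=7, low_voltage=1.6, high_voltage=20.0,
        frequency_mhz=18.0, focus_depth_mm=6.0, n_half_cycles=4,
        accumulations=1, beams_per_transmit=3,
    ),
    "L22-14v ex vivo": AcquisitionConfig(
        transducer_id="L22-14v", mode="burst_star_exvivo",
        n_low_frames=1, n_high_frames=7, low_voltage=1.6, high_voltage=25.0,
        frequency_mhz=18.0, focus_depth_mm=8.0, n_half_cycles=6,
        accumulations=1, beams_per_transmit=3,
    ),
}


def build_schedule(config_name: str) -> AcquisitionConfig:
    """Return a named acquisition schedule.

    Raises ``KeyError`` listing the known names if ``config_name`` is unknown.
    """
    try:
        return SCHEDULES[config_name]
    except KeyError:
        raise KeyError(
            f"unknown schedule {config_name!r}; known: {sorted(SCHEDULES)}"
        ) from None


@dataclass(frozen=True)
class ScanPlan:
    """Stage-scan grid: lateral (across-body) x longitudinal (head-to-tail) steps."""

    lateral_steps: int
    lateral_step_mm: float
    longitudinal_steps: int
    longitudinal_step_mm: float
    start_landmark: str = "rib cage"

    def __post_init__(self) -> None:
        if self.lateral_steps < 1 or self.longitudinal_steps < 1:
            raise ValueError("step counts must be >= 1")
        if self.lateral_step_mm <= 0 or self.longitudinal_step_mm <= 0:
            raise ValueError("step sizes must be positive")

    @property
    def n_positions(self) -> int:
        return self.lateral_steps * self.longitudinal_steps

    def positions(self):
        """Planned stage positions in row-major order (longitudinal outer)."""
        return [
            (i, j)
            for j in range(self.longitudinal_steps)
            for i in range(self.lateral_steps)
        ]


def plan_in_vivo_scan(
    lateral_steps: int = 3,
    lateral_step_mm: float = 9.6,
    longitudinal_steps: int = 80,
    longitudinal_step_mm: float = 0.5,
) -> ScanPlan:
    """Whole-abdomen scan plan; defaults give the 3 x 80 = 240 acquisition grid."""
    return ScanPlan(lateral_steps, lateral_step_mm, longitudinal_steps, longitudinal_step_mm)


def transmit_event_count(n_ray_lines: int, beams_per_transmit: int) -> int:
    """Transmit events needed to cover ``n_ray_lines`` when ``beams_per_transmit``
    focused beams are fired simultaneously (frame rate scales inversely)."""
    if n_ray_lines < 1 or beams_per_transmit < 1:
        raise ValueError("ray-line and beam counts must be >= 1")
    return math.ceil(n_ray_lines / beams_per_transmit)


@dataclass(frozen=True)
class DisplayParams:
    """Colormap-limit constants for comparative display.

    The lower display limit is the constant ``A`` (in units of the set-average
    background); the upper limit is ``B`` times the set-wide maximum divided by
    the set-average background.
    """

    A: float
    B: float
    mode: str  # burst | xam
    transducer_id: str

    def __post_init__(self) -> None:
        if self.A <= 0 or self.B <= 0:
            raise ValueError("display constants must be positive")


DISPLAY_CONSTANTS = {
    ("burst", "L22-14v"): DisplayParams(A=3.0, B=1.0, mode="burst", transducer_id="L22-14v"),
    ("burst", "L22-14vX"): DisplayParams(A=2.0, B=0.5, mode="burst", transducer_id="L22-14vX"),
    ("xam", "L22-14v"): DisplayParams(A=2.0, B=0.5, mode="xam", transducer_id="L22-14v"),
    ("xam", "L22-14vX"): DisplayParams(A=2.0, B=0.4, mode="xam", transducer_id="L22-14vX"),
}


def display_constants(mode: str, transducer_id: str) -> DisplayParams:
    """Look up the (A, B) display constants for an imaging mode and transducer."""
    try:
        return DISPLAY_CONSTANTS[(mode, transducer_id)]
    except KeyError:
        raise KeyError(f"no display constants for mode={mode!r}, transducer={transducer_id!r}") from None
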