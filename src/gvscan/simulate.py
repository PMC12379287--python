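"""Synthetic acquisition, titration, plate and flow-cytometry generators.

Everything downstream of this module (reconstruction, assembly,
quantification, fitting, screening, assay statistics) is exercised against
scenes generated here, whose ground truth is known exactly.

Signal model for an acquisition
-------------------------------
A beamformed envelope frame ``f`` at pixel ``p`` is

    I_f(p) = background(p) * S(p) + gv(p) * c_f + eps_f(p)

where ``S`` is one multiplicative, unit-mean, right-skewed speckle
realization held fixed across frames (collapse differencing relies on
frame-to-frame speckle correlation), ``gv`` is the gas-vesicle contrast
amplitude map, ``c_f`` is the per-frame collapse multiplier (a small
pre-collapse visibility on low-voltage frames, the collapse profile on
collapsing frames), and ``eps`` is independent zero-mean Gaussian noise.

For GI-mode (BURST*) profiles the vesicle-specific signal rises from the
first to the second collapsing frame and then decays to zero; for the
in vitro BURST profile the first collapsing frame is the brightest and the
last is fully collapsed. Breathing-like motion is modelled as a rigid
translation of a frame plus partial replacement of its speckle with a fresh
realization (speckle decorrelation).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage

from .config import AcquisitionConfig, ScanPlan

__all__ = [
    "MotionEvent",
    "SceneTruth",
    "FrameStack",
    "ScanSet",
    "VolumeTruth",
    "default_collapse_profile",
    "speckle_field",
    "simulate_acquisition",
    "simulate_scan",
    "simulate_dose_response",
    "simulate_patch_plate",
    "simulate_flow_sample",
    "hill",
]

# Pre-collapse gas-vesicle visibility on low-voltage frames, as a fraction of
# the first collapsing-frame multiplier c_1.
PRECOLLAPSE_VISIBILITY = 0.1

# Default collapse profiles. Magnitudes are free model parameters; only the
# orderings (rise from c1 to c2 then decay for the GI modes; monotone decay
# to zero for the in vitro mode) are constrained by the physics.
BURST_STAR_PROFILE = (0.6, 1.0, 0.5, 0.25, 0.1, 0.05, 0.0)


def default_collapse_profile(mode: str, n_high_frames: int) -> np.ndarray:
    """Per-collapsing-frame gas-vesicle signal multipliers for a mode.

    ``burst_star_*`` modes rise from the first to the second collapsing frame
    then decay to zero; ``burst_invitro`` decays geometrically from 1 to 0.
    """
    if mode in ("burst_star_invivo", "burst_star_exvivo"):
        base = np.asarray(BURST_STAR_PROFILE, dtype=float)
        if n_high_frames == base.size:
            return base.copy()
        if n_high_frames < 2:
            raise ValueError("need >= 2 collapsing frames")
        # resample the canonical 7-frame shape, pinning c2 > c1 and c_end = 0
        x = np.linspace(0.0, 1.0, n_high_frames)
        xp = np.linspace(0.0, 1.0, base.size)
        return np.interp(x, xp, base)
    if mode == "burst_invitro":
        # first collapsing frame brightest, last fully collapsed
        prof = 0.5 ** np.arange(n_high_frames, dtype=float)
        prof[-1] = 0.0
        return prof
    raise ValueError(f"unknown mode {mode!r}")


@dataclass(frozen=True)
class MotionEvent:
    """A breathing-like disturbance of one collapsing frame.

    ``frame_index`` indexes into the collapsing frames (0 = first collapsing
    frame). ``displacement_mm`` is (axial, lateral) rigid translation;
    ``decorrelation`` in [0, 1] is the fraction of the speckle replaced by a
    fresh realization.
    """

    frame_index: int
    displacement_mm: Tuple[float, float] = (0.0, 0.0)
    decorrelation: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.decorrelation <= 1.0:
            raise ValueError("decorrelation must be in [0, 1]")
        if self.frame_index < 0:
            raise ValueError("frame_index must be >= 0")


@dataclass
class SceneTruth:
    """Ground truth driving one simulated acquisition."""

    gv_map: np.ndarray
    background_map: np.ndarray
    collapse_profile: Optional[np.ndarray] = None  # default per mode if None
    motion_events: List[MotionEvent] = field(default_factory=list)
    speckle_scale: float = 1.0  # correlation length of the speckle, pixels; 0 disables
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.gv_map = np.asarray(self.gv_map, dtype=float)
        self.background_map = np.asarray(self.background_map, dtype=float)
        if self.gv_map.shape != self.background_map.shape:
            raise ValueError("gv_map and background_map must share shape")
        if np.any(self.gv_map < 0) or np.any(self.background_map < 0):
            raise ValueError("amplitude maps must be nonnegative")
        if self.collapse_profile is not None:
            self.collapse_profile = np.asarray(self.collapse_profile, dtype=float)


@dataclass
class FrameStack:
    """One acquisition position's frames plus schedule and provenance."""

    frames: np.ndarray  # [frame, axial, lateral], nonnegative envelope intensity
    voltages: np.ndarray
    config: AcquisitionConfig
    motion_flags: np.ndarray  # per-frame bool, ground truth for motion detectors
    position: Optional[Tuple[int, int]] = None  # (lateral_index, longitudinal_index)
    station: Optional[int] = None  # ex vivo length station
    truth: Optional[SceneTruth] = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.voltages = np.asarray(self.voltages, dtype=float)
        self.motion_flags = np.asarray(self.motion_flags, dtype=bool)
        if self.frames.ndim != 3:
            raise ValueError("frames must be [frame, axial, lateral]")
        n = self.config.n_frames
        if not (len(self.voltages) == self.frames.shape[0] == n == len(self.motion_flags)):
            raise ValueError("frame count inconsistent with schedule")

    @property
    def collapsing_frames(self) -> np.ndarray:
        """View of the frames acquired at the collapsing voltage."""
        return self.frames[self.config.n_low_frames:]


@dataclass
class ScanSet:
    """All acquisitions of one stage scan, keyed by planned position."""

    plan: ScanPlan
    stacks: Dict[Tuple[int, int], FrameStack]

    def __post_init__(self) -> None:
        planned = set(self.plan.positions())
        if set(self.stacks) != planned:
            raise ValueError("stacks must cover every planned position exactly once")


@dataclass
class VolumeTruth:
    """3-D ground-truth field sampled slab-by-slab by a stage scan.

    Arrays are [longitudinal_station, axial, lateral_full] where
    ``lateral_full`` spans all lateral stage positions side by side.
    """

    gv: np.ndarray
    background: np.ndarray
    noise_sd: float = 0.0
    speckle_scale: float = 1.0

    def __post_init__(self) -> None:
        self.gv = np.asarray(self.gv, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.gv.shape != self.background.shape:
            raise ValueError("gv and background must share shape")


def speckle_field(shape: Tuple[int, int], scale: float, rng: np.random.Generator) -> np.ndarray:
    """One unit-mean, right-skewed multiplicative speckle realization.

    Squared magnitude of a smoothed complex circular Gaussian field
    (fully developed speckle follows an exponential intensity law; smoothing
    sets the correlation length ``scale`` in pixels).
    """
    if scale <= 0:
        return np.ones(shape)
    z = rng.standard_normal(shape) + 1j * rng.standard_normal(shape)
    if scale > 0.5:
        z = ndimage.gaussian_filter(z.real, scale) + 1j * ndimage.gaussian_filter(z.imag, scale)
    s = np.abs(z) ** 2
    return s / s.mean()


def _frame_multipliers(config: AcquisitionConfig, profile: np.ndarray) -> np.ndarray:
    """Per-frame gas-vesicle multiplier: c_low on low-voltage frames, the
    collapse profile on collapsing frames."""
    c_low = PRECOLLAPSE_VISIBILITY * profile[0]
    return np.concatenate([np.full(config.n_low_frames, c_low), profile])


def simulate_acquisition(config: AcquisitionConfig, scene: SceneTruth) -> FrameStack:
    """Simulate one multi-frame acquisition under the stated signal model.

    Deterministic: identical (config, scene incl. seed) give bitwise-identical
    stacks. Frames named in ``scene.motion_events`` are rigidly shifted and
    partially speckle-decorrelated, and their motion flags are set (flags are
    ground truth for detector tests, not consumed by reconstruction).
    """
    profile = scene.collapse_profile
    if profile is None:
        profile = default_collapse_profile(config.mode, config.n_high_frames)
    profile = np.asarray(profile, dtype=float)
    if profile.size != config.n_high_frames:
        raise ValueError("collapse profile length must equal n_high_frames")
    if config.mode.startswith("burst_star"):
        if not (profile[1] > profile[0] and profile[-1] <= profile[0]):
            raise ValueError("burst_star profile must rise c1->c2 then decay below c1")
    else:
        if not profile[0] > profile[-1]:
            raise ValueError("burst_invitro profile must decay from c1 to cK")

    rng = np.random.default_rng(scene.seed)
    shape = scene.background_map.shape
    speckle = speckle_field(shape, scene.speckle_scale, rng)
    mults = _frame_multipliers(config, profile)
    motion_by_frame = {
        config.n_low_frames + ev.frame_index: ev for ev in scene.motion_events
    }
    for fidx in motion_by_frame:
        if fidx >= config.n_frames:
            raise ValueError("motion event frame_index outside collapsing frames")

    # In vitro frames are 50-accumulation averages; modelled as noise-sd
    # reduction by sqrt(accumulations) rather than explicit sub-frames.
    eff_sd = scene.noise_sd / np.sqrt(config.accumulations)

    frames = np.empty((config.n_frames,) + shape)
    flags = np.zeros(config.n_frames, dtype=bool)
    for f in range(config.n_frames):
        ev = motion_by_frame.get(f)
        if ev is None:
            bg = scene.background_map * speckle
            gv = scene.gv_map * mults[f]
            frame = bg + gv
        else:
            fresh = speckle_field(shape, scene.speckle_scale, rng)
            blended = (1.0 - ev.decorrelation) * speckle + ev.decorrelation * fresh
            frame = scene.background_map * blended + scene.gv_map * mults[f]
            shift_px = (
                ev.displacement_mm[0] / config.axial_spacing,
                ev.displacement_mm[1] / config.lateral_spacing,
            )
            if any(s != 0 for s in shift_px):
                frame = ndimage.shift(frame, shift_px, order=1, mode="nearest")
            flags[f] = True
        if eff_sd > 0:
            frame = frame + rng.normal(0.0, eff_sd, shape)
        frames[f] = np.clip(frame, 0.0, None)  # envelope intensities are nonnegative

    return FrameStack(
        frames=frames,
        voltages=np.asarray(config.voltages),
        config=config,
        motion_flags=flags,
        truth=scene,
    )


def simulate_scan(
    plan: ScanPlan,
    volume_truth: VolumeTruth,
    config: AcquisitionConfig,
    seed: int = 0,
    motion_positions: Optional[Dict[Tuple[int, int], List[MotionEvent]]] = None,
) -> ScanSet:
    """Simulate a full stage scan: one acquisition per planned position.

    ``volume_truth`` arrays must have ``longitudinal_steps`` stations and a
    lateral extent of ``lateral_steps`` times the per-acquisition image width.
    Each position (i, j) images the slab ``[j, :, i*w:(i+1)*w]``.
    """
    n_long, n_ax, n_lat_full = volume_truth.gv.shape
    if n_long != plan.longitudinal_steps:
        raise ValueError("volume truth longitudinal extent does not match plan")
    if n_lat_full % plan.lateral_steps:
        raise ValueError("volume truth lateral extent not divisible by lateral steps")
    width = n_lat_full // plan.lateral_steps
    motion_positions = motion_positions or {}

    ss = np.random.SeedSequence(seed)
    child_seeds = ss.generate_state(plan.n_positions)
    stacks: Dict[Tuple[int, int], FrameStack] = {}
    for k, (i, j) in enumerate(plan.positions()):
        scene = SceneTruth(
            gv_map=volume_truth.gv[j, :, i * width:(i + 1) * width],
            background_map=volume_truth.background[j, :, i * width:(i + 1) * width],
            motion_events=list(motion_positions.get((i, j), [])),
            speckle_scale=volume_truth.speckle_scale,
            noise_sd=volume_truth.noise_sd,
            seed=int(child_seeds[k]),
        )
        stack = simulate_acquisition(config, scene)
        stack.position = (i, j)
        stacks[(i, j)] = stack
    return ScanSet(plan=plan, stacks=stacks)


def hill(c, y0: float, ymax: float, K: float, n: float):
    """Hill dose-response: y(c) = y0 + (ymax - y0) * c^n / (K^n + c^n)."""
    c = np.asarray(c, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(c > 0, c ** n / (K ** n + c ** n), 0.0)
    return y0 + (ymax - y0) * frac


def simulate_dose_response(
    y0: float,
    ymax: float,
    half_max_conc: float,
    hill_n: float,
    conc_list: Sequence[float],
    n_reps: int = 4,
    noise_cv: float = 0.1,
    seed: int = 0,
) -> pd.DataFrame:
    """Replicate titration table: Hill curve values with multiplicative
    CV-scaled noise, clipped at zero.

    Returns a tidy frame with columns ``concentration_um``, ``replicate``,
    ``response``.
    """
    if y0 < 0 or not ymax > y0 or half_max_conc <= 0 or hill_n <= 0:
        raise ValueError("invalid Hill parameters")
    if n_reps < 1 or noise_cv < 0:
        raise ValueError("invalid replicate settings")
    rng = np.random.default_rng(seed)
    rows = []
    for c in conc_list:
        mu = float(hill(c, y0, ymax, half_max_conc, hill_n))
        for r in range(n_reps):
            val = mu * (1.0 + noise_cv * rng.standard_normal()) if noise_cv > 0 else mu
            rows.append({"concentration_um": float(c), "replicate": r, "response": max(val, 0.0)})
    return pd.DataFrame(rows)


def simulate_patch_plate(
    n_patches: int,
    parent_anchors: Tuple[float, float],
    variant_effects: Sequence[float],
    noise: float = 0.0,
    seed: int = 0,
    patch_radius: int = 8,
    pitch: int = 32,
    background_level: float = 50.0,
    background_gradient: Tuple[float, float] = (0.0, 0.0),
) -> Tuple[np.ndarray, pd.DataFrame]:
    """Grayscale patch-plate image plus an ROI table.

    Patches are disks laid out on a grid over a spatially varying background
    (``background_level`` plus a linear gradient per pixel). Each patch's mean
    intensity above local background equals its entry in ``variant_effects``
    (the parent anchors are the corrected opacities of the parent strain at 0
    and 1 mM inducer). The ROI table pairs every patch with an adjacent
    background disk.
    """
    a0, a1 = parent_anchors
    if not a1 > a0:
        raise ValueError("1 mM anchor must exceed 0 mM anchor")
    if len(variant_effects) != n_patches:
        raise ValueError("one effect per patch required")
    from skimage.draw import disk as draw_disk

    n_cols = int(np.ceil(np.sqrt(n_patches)))
    n_rows = int(np.ceil(n_patches / n_cols))
    h = n_rows * pitch + pitch
    w = n_cols * pitch + pitch
    if 2 * patch_radius + 4 >= pitch:
        raise ValueError("patches would overlap at this pitch")

    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0:h, 0:w]
    img = background_level + background_gradient[0] * yy + background_gradient[1] * xx
    if noise > 0:
        img = img + rng.normal(0.0, noise, img.shape)

    rows = []
    for k in range(n_patches):
        r, c = divmod(k, n_cols)
        cy = pitch // 2 + r * pitch + patch_radius
        cx = pitch // 2 + c * pitch + patch_radius
        rr, cc = draw_disk((cy, cx), patch_radius, shape=img.shape)
        img[rr, cc] += variant_effects[k]
        # adjacent background ROI: a disk offset laterally, inside the cell
        bx = cx + 2 * patch_radius + 2
        rows.append({
            "patch_id": k,
            "patch_cy": cy, "patch_cx": cx, "patch_radius": patch_radius,
            "bg_cy": cy, "bg_cx": bx, "bg_radius": max(patch_radius // 2, 2),
        })
    return img, pd.DataFrame(rows)


def simulate_flow_sample(
    n_events: int,
    frac_positive: float,
    neg_mean: float = 100.0,
    pos_mean: float = 20000.0,
    spread: float = 0.5,
    mcherry_frac: float = 0.95,
    seed: int = 0,
) -> pd.DataFrame:
    """Flow-cytometry event table with a bimodal GFP (B1) distribution.

    FSC-A/SSC-A are log-normal scatter typical of the gated bacterial
    population; Y2 (mCherry) is bimodal with ``mcherry_frac`` positive; B1
    (GFP) is a two-component log-normal mixture with positive weight
    ``frac_positive`` ("unflipped" vs "flipped" populations). ``spread`` is
    the log-normal sigma (natural log).
    """
    for f in (frac_positive, mcherry_frac):
        if not 0.0 <= f <= 1.0:
            raise ValueError("fractions must lie in [0, 1]")
    if n_events < 1:
        raise ValueError("need at least one event")
    rng = np.random.default_rng(seed)
    is_pos = rng.random(n_events) < frac_positive
    b1 = np.where(
        is_pos,
        rng.lognormal(np.log(pos_mean), spread, n_events),
        rng.lognormal(np.log(neg_mean), spread, n_events),
    )
    is_mch = rng.random(n_events) < mcherry_frac
    y2 = np.where(
        is_mch,
        rng.lognormal(np.log(5000.0), spread, n_events),
        rng.lognormal(np.log(50.0), spread, n_events),
    )
    fsc = rng.lognormal(np.log(3e4), 0.35, n_events)
    ssc = rng.lognormal(np.log(1e4), 0.35, n_events)
    return pd.DataFrame({
        "FSC-A": fsc, "SSC-A": ssc, "Y2": y2, "B1": b1,
        "truth_positive": is_pos,
    })
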