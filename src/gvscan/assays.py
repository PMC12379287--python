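"""Supporting assay statistics: fecal CFU, flow-cytometry gating, and
internal-standard-normalized thiosulfate quantification.

CFU per gram of feces comes from drop-plate colony counts scaled by the
serial dilution, plated volume, and fecal homogenate density. Flow events
are gated on FSC-A/SSC-A scatter plus positive mCherry (Y2); gated GFP (B1)
statistics are the geometric mean and the fraction of events strictly above
1000. Ion-chromatography thiosulfate peak areas are normalized by the
phosphate internal-standard area and converted to concentration through a
linear external standard curve.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "PlateCount",
    "FlowGates",
    "cfu_per_gram",
    "mutant_fraction",
    "gate_and_summarize",
    "fd_bins",
    "thiosulfate_conc",
]

GFP_POSITIVE_THRESHOLD = 1000.0  # B1 channel units; strictly greater counts
GEOMEAN_EPSILON = 1.0  # floor for nonpositive channel values before log


@dataclass(frozen=True)
class PlateCount:
    """One drop-plate count with its dilution bookkeeping."""

    colonies: int
    serial_dilution_factor: float  # overall, e.g. 1e-5
    plated_volume_ml: float
    homogenate_density_g_per_ml: float  # g feces per mL homogenate

    def __post_init__(self) -> None:
        if self.colonies < 0:
            raise ValueError("colony count must be nonnegative")
        if min(self.serial_dilution_factor, self.plated_volume_ml,
               self.homogenate_density_g_per_ml) <= 0:
            raise ValueError("dilution, volume and density must be positive")


def cfu_per_gram(pc: PlateCount) -> Tuple[float, float]:
    """CFU per gram of feces, plus the one-colony limit of detection.

    CFU/g = colonies / (plated volume * dilution factor * homogenate density).
    A zero count reports 0 CFU/g with the LOD (one colony equivalent) as the
    detection floor.
    """
    denom = pc.plated_volume_ml * pc.serial_dilution_factor * pc.homogenate_density_g_per_ml
    lod = 1.0 / denom
    return pc.colonies / denom, lod


def mutant_fraction(total_colonies_on_inducer: int, non_expressing_colonies: int) -> float:
    """Fraction of colonies that failed to express reporter genes on inducer plates."""
    if total_colonies_on_inducer <= 0:
        raise ValueError("total colony count must be positive")
    if not 0 <= non_expressing_colonies <= total_colonies_on_inducer:
        raise ValueError("non-expressing count must be within [0, total]")
    return non_expressing_colonies / total_colonies_on_inducer


@dataclass(frozen=True)
class FlowGates:
    """Rectangular scatter gate plus an mCherry positivity threshold."""

    fsc_range: Tuple[float, float] = (1e3, 1e6)
    ssc_range: Tuple[float, float] = (1e2, 1e6)
    mcherry_min: float = 1000.0  # Y2 threshold for mCherry-positive


def gate_and_summarize(
    events: pd.DataFrame, gates: FlowGates = FlowGates()
) -> Tuple[int, float, float]:
    """Gate on FSC-A/SSC-A and positive mCherry; summarize GFP.

    Returns (gated event count, GFP geometric mean, GFP-positive fraction).
    The geometric mean floors nonpositive B1 values at a small epsilon
    before taking logs; the positive fraction counts events strictly above
    the 1000-unit B1 threshold among all gated events.
    """
    req = {"FSC-A", "SSC-A", "Y2", "B1"}
    if not req.issubset(events.columns):
        raise ValueError(f"event table needs columns {sorted(req)}")
    sel = (
        events["FSC-A"].between(*gates.fsc_range)
        & events["SSC-A"].between(*gates.ssc_range)
        & (events["Y2"] > gates.mcherry_min)
    )
    gated = events.loc[sel, "B1"].to_numpy(dtype=float)
    if gated.size == 0:
        raise ValueError("zero gated events: statistics undefined")
    floored = np.maximum(gated, GEOMEAN_EPSILON)
    geo_mean = float(np.exp(np.mean(np.log(floored))))
    frac_pos = float(np.mean(gated > GFP_POSITIVE_THRESHOLD))
    return int(gated.size), geo_mean, frac_pos


def fd_bins(values: Sequence[float], min_bins: int = 100) -> Tuple[int, np.ndarray]:
    """Freedman-Diaconis histogram binning with a floor on the bin count.

    Bin width = 2 * IQR * n^(-1/3); count = range / width rounded up, never
    below ``min_bins``. Constant data (zero IQR or zero range) fall back to
    the floor count.
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size < 2:
        raise ValueError("need at least two finite values")
    iqr = float(np.subtract(*np.percentile(v, [75, 25])))
    rng = float(v.max() - v.min())
    if iqr <= 0 or rng <= 0:
        count = min_bins
    else:
        width = 2.0 * iqr * v.size ** (-1.0 / 3.0)
        count = max(math.ceil(rng / width), min_bins)
    edges = np.linspace(v.min(), v.max() if rng > 0 else v.min() + 1.0, count + 1)
    return count, edges


def thiosulfate_conc(
    records: pd.DataFrame,
    standards: pd.DataFrame,
) -> pd.DataFrame:
    """Thiosulfate concentration per sample via the phosphate-normalized
    external standard curve.

    ``records`` columns: sample_id, thiosulfate_peak_area, phosphate_peak_area,
    dilution_factor (technical replicates are rows sharing a sample_id).
    ``standards`` columns: concentration_um, normalized_area. An ordinary
    least-squares line (not forced through the origin) maps normalized area
    to concentration; the inverse prediction is scaled by the dilution
    factor and technical replicates are averaged per sample. Samples whose
    normalized area falls outside the standard range are flagged as
    extrapolated.
    """
    for col in ("sample_id", "thiosulfate_peak_area", "phosphate_peak_area", "dilution_factor"):
        if col not in records.columns:
            raise ValueError(f"records missing column {col!r}")
    for col in ("concentration_um", "normalized_area"):
        if col not in standards.columns:
            raise ValueError(f"standards missing column {col!r}")
    if len(standards) < 3:
        raise ValueError("need at least three standards")
    if (records["phosphate_peak_area"] <= 0).any():
        raise ValueError("phosphate areas must be positive")

    slope, intercept = np.polyfit(
        standards["normalized_area"].to_numpy(), standards["concentration_um"].to_numpy(), 1
    )
    lo, hi = standards["normalized_area"].min(), standards["normalized_area"].max()

    recs = records.copy()
    recs["normalized_area"] = recs["thiosulfate_peak_area"] / recs["phosphate_peak_area"]
    recs["conc_um"] = (slope * recs["normalized_area"] + intercept) * recs["dilution_factor"]
    recs["extrapolated"] = ~recs["normalized_area"].between(lo, hi)

    out = recs.groupby("sample_id").agg(
        concentration_um=("conc_um", "mean"),
        n_technical=("conc_um", "size"),
        extrapolated=("extrapolated", "any"),
    ).reset_index()
    return out
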