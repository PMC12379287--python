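"""Hill dose-response fitting, maximal fold change and detection limits.

Biosensor titrations (ultrasound SBR, GFP fluorescence or patch opacity
versus inducer concentration) are fitted with a four-parameter Hill model

    y(c) = y0 + (ymax - y0) * c^n / (K^n + c^n)

with baseline y0, saturating response ymax, half-maximum constant K (uM)
and cooperativity n. Maximal fold change is reported both empirically (max
condition mean over the zero-dose mean) and from the fitted curve
(ymax / y0). The cell-density detection limit is the lowest density whose
mean signal exceeds the blank mean plus three blank standard deviations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .simulate import hill

__all__ = [
    "DoseResponseData",
    "HillFit",
    "fit_hill",
    "max_fold_change",
    "detection_limit",
]


@dataclass
class DoseResponseData:
    """Replicate responses per concentration (concentrations in uM, increasing)."""

    concentration_um: np.ndarray
    replicate_values: List[np.ndarray]  # one array of replicates per concentration

    def __post_init__(self) -> None:
        self.concentration_um = np.asarray(self.concentration_um, dtype=float)
        self.replicate_values = [np.asarray(v, dtype=float) for v in self.replicate_values]
        if len(self.concentration_um) != len(self.replicate_values):
            raise ValueError("one replicate set per concentration required")
        if np.any(self.concentration_um < 0):
            raise ValueError("concentrations must be nonnegative")
        if np.any(np.diff(self.concentration_um) <= 0):
            raise ValueError("concentrations must be strictly increasing")

    @classmethod
    def from_table(cls, table: pd.DataFrame) -> "DoseResponseData":
        """Build from a tidy table with columns concentration_um, response."""
        groups = table.groupby("concentration_um")["response"]
        concs = sorted(groups.groups)
        return cls(
            concentration_um=np.asarray(concs),
            replicate_values=[groups.get_group(c).to_numpy() for c in concs],
        )

    @property
    def means(self) -> np.ndarray:
        return np.asarray([v.mean() for v in self.replicate_values])

    def flat(self) -> Tuple[np.ndarray, np.ndarray]:
        c = np.concatenate([
            np.full(len(v), ci) for ci, v in zip(self.concentration_um, self.replicate_values)
        ])
        y = np.concatenate(self.replicate_values)
        return c, y


@dataclass
class HillFit:
    """Fitted Hill parameters and derived quantities."""

    y0: float
    ymax: float
    K: Optional[float]  # None when unidentifiable (flat data)
    n: Optional[float]
    fold_change: float  # fitted-curve variant ymax / y0
    residual_rms: float
    unidentifiable: bool = False
    flags: List[str] = field(default_factory=list)

    def predict(self, c):
        if self.unidentifiable or self.K is None:
            return np.full_like(np.asarray(c, dtype=float), self.y0)
        return hill(c, self.y0, self.ymax, self.K, self.n)


# multi-start grid resolution for (K, n); deterministic, documented tie-break
_N_GRID = (0.5, 1.0, 2.0, 4.0)


def fit_hill(data: DoseResponseData, min_concentrations: int = 4) -> HillFit:
    """Deterministic least-squares Hill fit.

    A fixed multi-start grid over (K, n) seeds trust-region least squares;
    the best-residual solution wins, ties broken by the smallest K. Flat
    responses (no spread beyond numerical noise relative to the mean) are
    flagged unidentifiable with K and n not determined and fold change 1.
    """
    if len(data.concentration_um) < min_concentrations:
        raise ValueError(f"need >= {min_concentrations} distinct concentrations")
    c, y = data.flat()
    if np.any(y < 0):
        raise ValueError("responses must be nonnegative")

    means = data.means
    spread = means.max() - means.min()
    scale = max(abs(means).max(), 1e-12)
    if spread <= 1e-9 * scale:
        return HillFit(
            y0=float(means.mean()), ymax=float(means.mean()), K=None, n=None,
            fold_change=1.0, residual_rms=float(np.std(y)), unidentifiable=True,
            flags=["flat response: K not determined"],
        )

    pos_c = data.concentration_um[data.concentration_um > 0]
    k_grid = np.geomspace(pos_c.min(), pos_c.max(), 7)
    y_lo, y_hi = float(min(means.min(), 0.0)), float(means.max())

    def resid(p):
        y0, ymax, logK, logn = p
        return hill(c, y0, ymax, np.exp(logK), np.exp(logn)) - y

    best = None  # (rms, K, params)
    for k0 in k_grid:
        for n0 in _N_GRID:
            p0 = np.array([means[0], means[-1], np.log(k0), np.log(n0)])
            try:
                sol = least_squares(
                    resid, p0,
                    bounds=([y_lo - scale, y_lo - scale, np.log(pos_c.min()) - 5, np.log(0.05)],
                            [y_hi + scale, y_hi + 10 * scale, np.log(pos_c.max()) + 5, np.log(20.0)]),
                    method="trf", xtol=1e-12, ftol=1e-12, gtol=1e-12,
                )
            except ValueError:
                continue
            rms = float(np.sqrt(np.mean(sol.fun ** 2)))
            K = float(np.exp(sol.x[2]))
            if best is None or rms < best[0] - 1e-12 * scale or (
                abs(rms - best[0]) <= 1e-12 * scale and K < best[1]
            ):
                best = (rms, K, sol.x)

    rms, K, p = best
    y0f, ymaxf = float(p[0]), float(p[1])
    nf = float(np.exp(p[3]))
    flags = []
    if ymaxf < y0f:
        flags.append("decreasing response: fitted ymax below y0")
    fold = ymaxf / y0f if y0f > 0 else np.inf
    return HillFit(y0=y0f, ymax=ymaxf, K=K, n=nf, fold_change=float(fold),
                   residual_rms=rms, flags=flags)


def max_fold_change(data: DoseResponseData) -> float:
    """Maximal fold change: max condition mean over the zero-dose mean.

    Requires a zero-concentration condition with positive mean (the fold
    change is anchored at the uninduced baseline).
    """
    if data.concentration_um[0] != 0.0:
        raise ValueError("zero-concentration condition required")
    baseline = data.means[0]
    if baseline <= 0:
        raise ValueError("zero-dose mean must be positive for fold change")
    return float(data.means.max() / baseline)


def detection_limit(
    density_series: pd.DataFrame,
    n_sd: float = 3.0,
) -> Tuple[Optional[float], float]:
    """Lowest cell density whose mean SBR exceeds blank mean + n_sd * blank SD.

    ``density_series`` needs columns ``cells_per_ml`` (with a 0 blank) and
    ``sbr``. Returns (detected density or None if never exceeded, criterion).
    """
    req = {"cells_per_ml", "sbr"}
    if not req.issubset(density_series.columns):
        raise ValueError(f"columns {sorted(req)} required")
    groups = density_series.groupby("cells_per_ml")["sbr"]
    densities = sorted(groups.groups)
    if densities[0] != 0:
        raise ValueError("a blank (0 cells/mL) condition is required")
    blank = groups.get_group(0)
    criterion = float(blank.mean() + n_sd * blank.std(ddof=1))
    for d in densities[1:]:
        if groups.get_group(d).mean() > criterion:
            return float(d), criterion
    return None, criterion
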