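"""Connectivity-vs-cost optimization statistics across D.

Each arbor variant contributes one :class:`MorphRecord` holding its
effective fractal dimension D, orientation-averaged profile P, and the
cost metrics A_s, A_b, V_b, V_m.  Across an ensemble the three
D-dependent curves — connectivity density P/A_b, operating cost A_s/A_b,
and building cost V_m/V_b — are summarized with 3rd-degree polynomial
fits, and the optimization indicators are the derivative ratios

    R_PA(D) = d/dD (P/A_b) / d/dD (A_s/A_b)
    R_PV(D) = d/dD (P/A_b) / d/dD (V_m/V_b)

whose peaks locate the D value at which connectivity gains grow fastest
relative to the respective cost.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .errors import ParameterError

__all__ = [
    "MorphRecord",
    "OptimizationCurves",
    "PeakResult",
    "records_frame",
    "binned_average",
    "fit_cubic",
    "compute_R",
    "find_peak",
    "fit_optimization_curves",
]

_METRICS = ("P_over_Ab", "As_over_Ab", "Vm_over_Vb")


@dataclass
class MorphRecord:
    """Measurements of one arbor variant (areas µm², volumes µm³)."""

    arbor_id: str
    manipulation: str       #: e.g. "weave", "fork", "both", "none", "weave_sigma"
    alpha: float            #: angle multiplier or generator parameter
    D: float
    P: float
    A_s: float
    A_b: float
    V_b: float
    V_m: float

    @property
    def P_over_As(self) -> float:
        return self.P / self.A_s

    @property
    def As_over_Ab(self) -> float:
        return self.A_s / self.A_b

    @property
    def P_over_Ab(self) -> float:
        return self.P / self.A_b

    @property
    def Vm_over_Vb(self) -> float:
        return self.V_m / self.V_b


def records_frame(records: list[MorphRecord]) -> pd.DataFrame:
    """Flat table of records with the derived ratios appended."""
    df = pd.DataFrame([asdict(r) for r in records])
    if len(df):
        df["P_over_As"] = df.P / df.A_s
        df["As_over_Ab"] = df.A_s / df.A_b
        df["P_over_Ab"] = df.P / df.A_b
        df["Vm_over_Vb"] = df.V_m / df.V_b
    return df


def binned_average(records: list[MorphRecord] | pd.DataFrame, metric: str,
                   n_bins: int = 15) -> pd.DataFrame:
    """Mean of ``metric`` in equal-width D bins (empty bins flagged NaN)."""
    df = records if isinstance(records, pd.DataFrame) else records_frame(records)
    if n_bins < 1:
        raise ParameterError("n_bins must be >= 1")
    if not len(df):
        raise ParameterError("no records")
    lo, hi = df.D.min(), df.D.max()
    if hi == lo:
        hi = lo + 1e-9
    edges = np.linspace(lo, hi, n_bins + 1)
    idx = np.clip(np.digitize(df.D, edges) - 1, 0, n_bins - 1)
    means = np.full(n_bins, np.nan)
    for b in range(n_bins):
        sel = idx == b
        if sel.any():
            means[b] = df.loc[sel, metric].mean()
    centers = 0.5 * (edges[:-1] + edges[1:])
    return pd.DataFrame({"D": centers, metric: means})


def fit_cubic(records: list[MorphRecord] | pd.DataFrame, metric: str) -> np.ndarray:
    """Least-squares cubic of ``metric`` on D; coefficients highest first."""
    df = records if isinstance(records, pd.DataFrame) else records_frame(records)
    if len(df) < 5:
        raise ParameterError("need at least 5 records for a cubic fit")
    if df.D.nunique() < 4:
        raise ParameterError("need at least 4 distinct D values (rank deficient)")
    return np.polyfit(df.D.to_numpy(), df[metric].to_numpy(), 3)


@dataclass
class OptimizationCurves:
    """Cubic fits of the three metrics vs D plus the data D range."""

    coeffs: dict  #: metric name -> (4,) polynomial coefficients
    D_range: tuple[float, float]
    binned: dict = field(default_factory=dict)

    def metric_poly(self, metric: str) -> np.poly1d:
        return np.poly1d(self.coeffs[metric])


def fit_optimization_curves(records: list[MorphRecord] | pd.DataFrame,
                            n_bins: int = 15) -> OptimizationCurves:
    df = records if isinstance(records, pd.DataFrame) else records_frame(records)
    coeffs = {m: fit_cubic(df, m) for m in _METRICS}
    binned = {m: binned_average(df, m, n_bins) for m in _METRICS}
    return OptimizationCurves(
        coeffs=coeffs,
        D_range=(float(df.D.min()), float(df.D.max())),
        binned=binned,
    )


def compute_R(curves: OptimizationCurves, which: str,
              D_grid: np.ndarray) -> np.ndarray:
    """Derivative ratio R_PA or R_PV on a D grid (masked where denom' = 0).

    The ratio is formed from the analytic derivatives of the fitted
    cubics; points where the denominator derivative vanishes are NaN.
    """
    if which == "R_PA":
        den_metric = "As_over_Ab"
    elif which == "R_PV":
        den_metric = "Vm_over_Vb"
    else:
        raise ParameterError("which must be 'R_PA' or 'R_PV'")
    num = np.polyder(np.poly1d(curves.coeffs["P_over_Ab"]))
    den = np.polyder(np.poly1d(curves.coeffs[den_metric]))
    D_grid = np.asarray(D_grid, dtype=float)
    dn = den(D_grid)
    out = np.full_like(D_grid, np.nan)
    ok = np.abs(dn) > 1e-12
    out[ok] = num(D_grid[ok]) / dn[ok]
    if not ok.any():
        raise ParameterError("denominator derivative vanishes on the whole grid")
    return out


@dataclass
class PeakResult:
    D_peak: float | None
    value: float | None
    interior: bool            #: True when the peak lies inside the data D range
    no_interior_peak: bool = False


def find_peak(R: np.ndarray, D_grid: np.ndarray,
              search_range: tuple[float, float] | None = None,
              data_range: tuple[float, float] | None = None) -> PeakResult:
    """Argmax of R on the grid, refined by 3-point quadratic interpolation.

    A maximum at the edge of the searched range (monotone R) is flagged
    ``no_interior_peak`` instead of reporting a location.
    """
    D_grid = np.asarray(D_grid, dtype=float)
    R = np.asarray(R, dtype=float)
    mask = np.isfinite(R)
    if search_range is not None:
        mask &= (D_grid >= search_range[0]) & (D_grid <= search_range[1])
    if mask.sum() < 3:
        raise ParameterError("need at least 3 finite grid points in range")
    idx = np.flatnonzero(mask)
    sub = idx[np.argmax(R[idx])]
    pos = np.searchsorted(idx, sub)
    if pos == 0 or pos == len(idx) - 1:
        return PeakResult(None, None, False, no_interior_peak=True)
    i0, i1, i2 = idx[pos - 1], idx[pos], idx[pos + 1]
    x = D_grid[[i0, i1, i2]]
    y = R[[i0, i1, i2]]
    a, b, _ = np.polyfit(x, y, 2)
    if a < 0:
        D_peak = float(-b / (2 * a))
        D_peak = float(np.clip(D_peak, x[0], x[2]))
    else:
        D_peak = float(x[1])
    val = float(np.interp(D_peak, D_grid[mask], R[mask]))
    interior = True
    if data_range is not None:
        interior = data_range[0] <= D_peak <= data_range[1]
    return PeakResult(D_peak, val, interior)
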