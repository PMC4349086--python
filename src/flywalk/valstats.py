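"""Method-validation statistics: robust agreement between two measurement
methods of the same flies.

Given paired measurements (reference/manual x, automated y) the report
fits a bi-square (Tukey biweight) robust linear regression, expresses
the fit residuals in percent of the reference value, and summarises
them with box-plot statistics using the 1.5-box-width outlier rule,
alongside the plain Pearson correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

TUKEY_C = 4.685  # standard 95%-efficiency tuning constant


@dataclass
class BoxplotStats:
    median: float
    q25: float
    q75: float
    whisker_low: float
    whisker_high: float
    outlier_indices: list[int]


@dataclass
class AgreementReport:
    trait: str
    n: int
    r: float
    slope: float
    intercept: float
    converged: bool
    residuals_pct: np.ndarray
    mean_pct: float
    sd_pct: float
    box: BoxplotStats = field(repr=False)

    def row(self) -> dict:
        return {
            "trait": self.trait,
            "n": self.n,
            "r": self.r,
            "slope": self.slope,
            "intercept": self.intercept,
            "mean_pct": self.mean_pct,
            "sd_pct": self.sd_pct,
            "median_pct": self.box.median if self.box else float("nan"),
            "q25_pct": self.box.q25 if self.box else float("nan"),
            "q75_pct": self.box.q75 if self.box else float("nan"),
            "n_outliers": len(self.box.outlier_indices) if self.box else 0,
        }


def tukey_weights(scaled_residuals: np.ndarray, c: float = TUKEY_C) -> np.ndarray:
    """Bisquare weights in [0, 1]; exactly 0 beyond the tuning constant."""
    u = np.abs(np.asarray(scaled_residuals, dtype=float)) / c
    w = np.zeros_like(u)
    inside = u < 1.0
    w[inside] = (1.0 - u[inside] ** 2) ** 2
    return w


def bisquare_regression(
    x: np.ndarray,
    y: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 50,
) -> tuple[float, float, np.ndarray, bool]:
    """IRLS line fit with Tukey bisquare weights.

    The residual scale is re-estimated each iteration as MAD/0.6745.
    Returns (slope, intercept, final weights, converged).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("x is constant")
    # OLS start
    slope, intercept = np.polyfit(x, y, 1)
    w = np.ones_like(x)
    converged = False
    # scale floor: when the bulk of the data fits exactly the MAD of the
    # residuals degenerates to (numerical) zero, and dividing round-off
    # residuals by a round-off scale would flag every point as an outlier
    scale_floor = 1e-8 * max(1.0, float(np.median(np.abs(y))))
    for _ in range(max_iter):
        resid = y - (slope * x + intercept)
        # MAD centred at zero: the fit has an intercept, so residuals of a
        # good fit centre themselves, and a zero centre keeps a gross
        # outlier from shifting the reference point
        mad = np.median(np.abs(resid))
        scale = max(mad / 0.6745, scale_floor)
        w = tukey_weights(resid / scale)
        if w.sum() == 0 or np.count_nonzero(w) < 2:
            break
        sw = np.sqrt(w)
        A = np.column_stack([x * sw, sw])
        coef, *_ = np.linalg.lstsq(A, y * sw, rcond=None)
        new_slope, new_intercept = float(coef[0]), float(coef[1])
        if abs(new_slope - slope) < tol and abs(new_intercept - intercept) < tol:
            slope, intercept = new_slope, new_intercept
            converged = True
            break
        slope, intercept = new_slope, new_intercept
    return float(slope), float(intercept), w, converged


def percent_residuals(
    x: np.ndarray, y: np.ndarray, slope: float, intercept: float, raw: bool = False
) -> np.ndarray:
    """Fit residuals in percent of the reference value.

    ``raw=True`` instead reports the plain difference (y - x) in percent
    of x, bypassing the regression.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.any(x <= 0):
        raise ValueError("reference values must be positive")
    if raw:
        return 100.0 * (y - x) / x
    return 100.0 * (y - (slope * x + intercept)) / x


def boxplot_stats(values: np.ndarray) -> BoxplotStats:
    """Quartiles (linear interpolation), whiskers and the 1.5 rule.

    Outliers lie more than 1.5 box widths below q25 or above q75;
    whiskers mark the most extreme non-outlier values.
    """
    v = np.asarray(values, dtype=float)
    if len(v) < 4:
        raise ValueError("need at least 4 values")
    q25, med, q75 = np.percentile(v, [25, 50, 75], method="linear")
    width = q75 - q25
    lo, hi = q25 - 1.5 * width, q75 + 1.5 * width
    outliers = np.flatnonzero((v < lo) | (v > hi))
    inside = v[(v >= lo) & (v <= hi)]
    return BoxplotStats(
        median=float(med),
        q25=float(q25),
        q75=float(q75),
        whisker_low=float(inside.min()),
        whisker_high=float(inside.max()),
        outlier_indices=outliers.tolist(),
    )


def pearson_r(x: np.ndarray, y: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input has no defined correlation")
    return float(stats.pearsonr(x, y).statistic)


def agreement_report(
    trait: str, manual: np.ndarray, auto: np.ndarray, raw: bool = False
) -> AgreementReport:
    """Full per-trait validation: robust fit + percent residual summary."""
    manual = np.asarray(manual, dtype=float)
    auto = np.asarray(auto, dtype=float)
    ok = np.isfinite(manual) & np.isfinite(auto)
    manual, auto = manual[ok], auto[ok]
    slope, intercept, _, converged = bisquare_regression(manual, auto)
    resid = percent_residuals(manual, auto, slope, intercept, raw=raw)
    return AgreementReport(
        trait=trait,
        n=len(manual),
        r=pearson_r(manual, auto),
        slope=slope,
        intercept=intercept,
        converged=converged,
        residuals_pct=resid,
        mean_pct=float(resid.mean()),
        sd_pct=float(resid.std(ddof=1)),
        box=boxplot_stats(resid) if len(resid) >= 4 else None,
    )


def validate_tables(
    manual: pd.DataFrame, auto: pd.DataFrame, traits: list[str], raw: bool = False
) -> pd.DataFrame:
    """Join two fly_id-keyed tables and report agreement per trait."""
    merged = manual.merge(auto, on="fly_id", suffixes=("_manual", "_auto"))
    rows = []
    for trait in traits:
        rep = agreement_report(
            trait,
            merged[f"{trait}_manual"].to_numpy(),
            merged[f"{trait}_auto"].to_numpy(),
            raw=raw,
        )
        rows.append(rep.row())
    return pd.DataFrame(rows)
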