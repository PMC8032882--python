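"""Double-sampling sward calibration and herbage bookkeeping.

A rising plate meter gives cheap compressed sward height (CSH, cm)
readings at 50 random points per paddock and date; occasional
destructive cuts pair CSH with herbage dry matter (g DM m-2). An OLS
line fitted to the pairs converts every CSH reading into predicted
herbage, from which per-paddock summaries follow: mean herbage on offer
(HO), its within-paddock standard deviation (SD herbage - the spatial
heterogeneity proxy), the CV, and the herbage allowance per livestock
unit (HA, kg DM LU-1).
"""

from __future__ import annotations

import datetime as dt
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .io_model import M2_PER_HA

__all__ = [
    "CalibrationModel",
    "HerbageSummary",
    "fit_calibration",
    "fit_calibrations",
    "predict_herbage",
    "herbage_summary",
    "summarise_predictions",
    "herbage_allowance",
    "sqrt_transform",
    "distance_heterogeneity_correlation",
]


@dataclass(frozen=True)
class CalibrationModel:
    """OLS line herbage = intercept + slope * CSH, with fit diagnostics."""

    scope: str  # e.g. a period id, or 'paddock x period' label
    intercept: float  # g DM m-2
    slope: float  # g DM m-2 cm-1
    n: int
    r2_adj: float
    rmse: float  # g DM m-2, sqrt(mean squared residual)
    se_intercept: float = float("nan")
    se_slope: float = float("nan")

    def conf_int(self, level: float = 0.95) -> dict[str, tuple[float, float]]:
        """Classical t confidence intervals for intercept and slope."""
        tcrit = stats.t.ppf(0.5 + level / 2.0, self.n - 2)
        return {
            "intercept": (
                self.intercept - tcrit * self.se_intercept,
                self.intercept + tcrit * self.se_intercept,
            ),
            "slope": (
                self.slope - tcrit * self.se_slope,
                self.slope + tcrit * self.se_slope,
            ),
        }


@dataclass(frozen=True)
class HerbageSummary:
    paddock_id: str
    date: dt.date | None
    mean_ho: float  # g DM m-2
    sd_ho: float  # g DM m-2 (SD herbage), sample SD
    cv: float
    n_points: int


def fit_calibration(csh, herbage, scope: str = "period") -> CalibrationModel:
    """Fit the CSH -> herbage calibration line by ordinary least squares.

    Requires >= 3 pairs (diagnostics need a residual degree of freedom)
    and non-degenerate CSH. ``r2_adj`` follows the one-regressor
    adjustment 1 - (1-R^2)(n-1)/(n-2); ``rmse`` is the root mean squared
    residual (n in the denominator).
    """
    csh = np.asarray(csh, dtype=float)
    herbage = np.asarray(herbage, dtype=float)
    if len(csh) != len(herbage):
        raise ValueError("csh and herbage length mismatch")
    n = len(csh)
    if n < 3:
        raise ValueError("need >= 3 calibration pairs")
    if np.ptp(csh) == 0:
        raise ValueError("zero CSH variance: calibration line undetermined")
    res = sm.OLS(herbage, sm.add_constant(csh)).fit()
    rmse = float(np.sqrt(np.mean(res.resid**2)))
    return CalibrationModel(
        scope=scope,
        intercept=float(res.params[0]),
        slope=float(res.params[1]),
        n=n,
        r2_adj=float(res.rsquared_adj),
        rmse=rmse,
        se_intercept=float(res.bse[0]),
        se_slope=float(res.bse[1]),
    )


def fit_calibrations(
    pairs: pd.DataFrame, by: str | list[str] | None = None
) -> dict[str, CalibrationModel]:
    """Fit one calibration per group of a calibration-pair table.

    ``pairs`` needs ``csh_cm`` and ``herbage_g_dm_m2`` columns. With
    ``by=None`` all pairs are pooled (the default scope: per period
    across paddocks, since 6-8 cuts per paddock are too few alone);
    pass ``by='paddock_id'`` for paddock-level fits.
    """
    if by is None:
        return {"pooled": fit_calibration(pairs["csh_cm"], pairs["herbage_g_dm_m2"], "pooled")}
    out = {}
    for key, g in pairs.groupby(by):
        label = key if isinstance(key, str) else "/".join(map(str, key))
        out[label] = fit_calibration(g["csh_cm"], g["herbage_g_dm_m2"], scope=str(label))
    return out


def predict_herbage(csh, model: CalibrationModel) -> np.ndarray:
    """Predicted herbage (g DM m-2) for CSH readings, floored at 0."""
    csh = np.asarray(csh, dtype=float)
    if np.any(csh < 0):
        raise ValueError("CSH must be >= 0")
    return np.maximum(model.intercept + model.slope * csh, 0.0)


def herbage_summary(
    values, paddock_id: str = "", date: dt.date | None = None
) -> HerbageSummary:
    """Mean, sample SD (the SD-herbage heterogeneity proxy) and CV of the
    predicted herbage values of one paddock-date."""
    values = np.asarray(values, dtype=float)
    n = len(values)
    mean = float(np.mean(values)) if n else float("nan")
    if n < 2:
        warnings.warn("fewer than 2 herbage values: SD undefined", stacklevel=2)
        sd = float("nan")
    else:
        sd = float(np.std(values, ddof=1))
    cv = sd / mean if n >= 2 and mean > 0 else float("nan")
    return HerbageSummary(paddock_id, date, mean, sd, cv, n)


def summarise_predictions(
    csh: pd.DataFrame, model: CalibrationModel
) -> pd.DataFrame:
    """Predict herbage at every plate-meter point and summarise per
    paddock-date. ``csh`` follows the csh.csv layout."""
    rows = []
    for (paddock_id, date), g in csh.groupby(["paddock_id", "date"]):
        pred = predict_herbage(g["csh_cm"], model)
        s = herbage_summary(pred, paddock_id=str(paddock_id), date=date)
        rows.append(
            {
                "paddock_id": s.paddock_id,
                "date": s.date,
                "mean_ho": s.mean_ho,
                "sd_ho": s.sd_ho,
                "cv": s.cv,
                "n_points": s.n_points,
            }
        )
    return pd.DataFrame(rows)


def herbage_allowance(mean_ho: float, area_m2: float, lu: float) -> float:
    """Herbage allowance, kg DM per livestock unit:
    mean HO (g m-2) x paddock area (m2) / 1000 / LU."""
    if lu <= 0:
        raise ValueError("LU must be > 0")
    if area_m2 <= 0:
        raise ValueError("area must be > 0")
    return mean_ho * area_m2 / 1000.0 / lu


def sqrt_transform(values) -> np.ndarray:
    """Element-wise square root (variance-stabilising step used before
    regressing allowance on treatment)."""
    values = np.asarray(values, dtype=float)
    if np.any(values < 0):
        raise ValueError("values must be >= 0")
    return np.sqrt(values)


def distance_heterogeneity_correlation(
    summaries: pd.DataFrame,
    distance_col: str = "daily_distance",
    sd_col: str = "sd_ho",
) -> tuple[float, float]:
    """Pearson correlation (r, p) between mean daily walking distance and
    SD herbage across treatment x period summaries. Exposed as an
    output; no reference value exists for it."""
    r, p = stats.pearsonr(summaries[distance_col], summaries[sd_col])
    return float(r), float(p)
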