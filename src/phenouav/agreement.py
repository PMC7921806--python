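"""Ground-vs-aerial agreement and outlier screening.

Pairs manual plot heights (PHground) with raster-derived ones (PHaerial).
Gross errors are screened with externally studentized residuals from the
regression of ground on aerial and a Bonferroni test at P < 0.01; the
flagged pairs are removed from both vectors before agreement statistics.

Two RMSEs are deliberately distinct: the residual RMSE of the fitted line
(scatter around the relationship) and the raw-difference RMSE
sqrt(mean((aerial - ground)^2)) (absolute deviation, which also absorbs
bias).  The cross-stage deviation ``rmse_dev`` pools raw squared
differences over all plot x stage pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["AgreementReport", "DeviationSummary", "flag_outliers", "agreement", "rmse_dev"]


@dataclass
class AgreementReport:
    n: int
    pearson_r: float
    r_squared: float
    slope: float
    intercept: float
    rmse_regression_cm: float  # residual RMSE of the fitted line
    rmse_difference_cm: float  # raw aerial-minus-ground RMSE
    bias_cm: float  # mean(aerial - ground)
    p_value: float  # slope test (equivalently the R^2 F-test here)
    outliers_removed: list = field(default_factory=list)

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        d["outliers_removed"] = list(self.outliers_removed)
        return d


@dataclass
class DeviationSummary:
    rmse_dev_cm: float
    per_stage: dict[str, dict]  # stage -> {"rmse_cm":..., "n":...}
    n_total: int


def studentized_residuals(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Externally studentized residuals of the simple regression y ~ x."""
    n = len(x)
    X = np.column_stack([np.ones(n), x])
    XtX_inv = np.linalg.inv(X.T @ X)
    H = X @ XtX_inv @ X.T
    h = np.diag(H)
    beta = XtX_inv @ (X.T @ y)
    resid = y - X @ beta
    sse = float(resid @ resid)
    # leave-one-out residual variance, p = 2 parameters
    s2_i = (sse - resid**2 / (1 - h)) / (n - 3)
    return resid / np.sqrt(np.maximum(s2_i * (1 - h), 1e-300))


def flag_outliers(
    ground, aerial, alpha: float = 0.01, ids=None, direction: str = "ground_on_aerial"
) -> list:
    """Bonferroni-screened gross errors in paired height vectors.

    Regresses ground on aerial (the manual measurement carries the gross
    errors; flip with ``direction="aerial_on_ground"``), studentizes each
    residual externally, and flags pairs whose two-sided t probability on
    n-3 degrees of freedom survives the Bonferroni correction p * n < alpha.
    Returns the ids (or indices) of flagged pairs.
    """
    g = np.asarray(ground, dtype=float)
    a = np.asarray(aerial, dtype=float)
    if g.shape != a.shape:
        raise ValueError("ground and aerial must be the same length")
    n = len(g)
    if n < 5:
        raise ValueError("need >= 5 paired values to screen outliers")
    if direction == "ground_on_aerial":
        x, y = a, g
    elif direction == "aerial_on_ground":
        x, y = g, a
    else:
        raise ValueError("direction must be 'ground_on_aerial' or 'aerial_on_ground'")
    if np.ptp(x) == 0:
        raise ValueError("regressor has zero variance; outlier screen undefined")
    t = studentized_residuals(x, y)
    p = 2.0 * stats.t.sf(np.abs(t), n - 3)
    flagged = np.nonzero(p * n < alpha)[0]
    if ids is None:
        return flagged.tolist()
    ids = list(ids)
    return [ids[i] for i in flagged]


def agreement(ground, aerial, outliers_removed: list | None = None) -> AgreementReport:
    """Simple-regression agreement between paired ground and aerial heights.

    Expects the outlier screen to have been applied (or skipped on
    purpose).  Reports the regression (slope, intercept, R^2, residual
    RMSE, slope-test p) plus raw-difference RMSE and bias.
    """
    g = np.asarray(ground, dtype=float)
    a = np.asarray(aerial, dtype=float)
    ok = np.isfinite(g) & np.isfinite(a)
    g, a = g[ok], a[ok]
    n = len(g)
    if n < 3:
        raise ValueError("need >= 3 pairs")
    fit = stats.linregress(g, a)
    resid = a - (fit.intercept + fit.slope * g)
    diff = a - g
    return AgreementReport(
        n=n,
        pearson_r=float(fit.rvalue),
        r_squared=float(fit.rvalue**2),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        rmse_regression_cm=float(np.sqrt(np.mean(resid**2))),
        rmse_difference_cm=float(np.sqrt(np.mean(diff**2))),
        bias_cm=float(np.mean(diff)),
        p_value=float(fit.pvalue),
        outliers_removed=list(outliers_removed or []),
    )


def rmse_dev(records: pd.DataFrame, stage_col: str = "stage") -> DeviationSummary:
    """Cross-stage deviation between aerial and ground heights.

    ``records`` needs columns ``ground_cm``, ``aerial_cm`` and a stage
    label; the pooled value is the root of the mean squared difference over
    every plot x stage pair, with a per-stage decomposition.
    """
    df = records.dropna(subset=["ground_cm", "aerial_cm"])
    if df.empty:
        raise ValueError("no paired records")
    sq = (df["aerial_cm"] - df["ground_cm"]) ** 2
    per_stage = {}
    for stage, grp in sq.groupby(df[stage_col]):
        per_stage[str(stage)] = {"rmse_cm": float(np.sqrt(grp.mean())), "n": int(len(grp))}
    return DeviationSummary(
        rmse_dev_cm=float(np.sqrt(sq.mean())),
        per_stage=per_stage,
        n_total=int(len(sq)),
    )
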