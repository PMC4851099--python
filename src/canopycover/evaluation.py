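"""Agreement statistics: linear regression reports and method comparison.

Validation of an LAI estimator against a reference is summarised by an
ordinary least-squares fit y = a + b x of estimated on true values,
reporting the coefficient of determination R^2, the slope b and intercept
a, the standard error of estimates (SEE, the residual standard error with
dof = n - 2, or n - 1 when the fit is forced through the origin), the
root mean squared error (RMSE, sqrt of the mean squared residual) and the
F-test p-value of the regression.  A perfect estimator gives b = 1,
a = 0, R^2 = 1, RMSE = 0.

:func:`compare_methods` produces one such report per k-estimation
strategy, the table used to rank the five strategies on a common set of
images.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = ["RegressionReport", "linear_fit", "compare_methods", "write_report_csv"]


@dataclass(frozen=True)
class RegressionReport:
    """Summary of one least-squares comparison."""

    slope_b: float
    intercept_a: float
    r2: float
    see: float
    rmse: float
    p_value: float
    n: int
    through_origin: bool = False


def linear_fit(
    x: Sequence[float], y: Sequence[float], through_origin: bool = False
) -> RegressionReport:
    """Ordinary least squares y = a + b x.

    Parameters
    ----------
    x, y : sequences of equal length >= 2
    through_origin : bool
        Force a = 0 (regression through the origin); R^2 is then the
        uncentred coefficient of determination.

    Raises
    ------
    ValueError
        On length mismatch or (for the intercept model) constant x.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError(f"x and y must be equal-length 1-D, got {x.shape}, {y.shape}")
    n = x.size
    if n < 2:
        raise ValueError(f"need at least 2 points, got {n}")
    if not through_origin and np.ptp(x) == 0.0:
        raise ValueError("x is constant; slope with intercept is undefined")

    design = x[:, None] if through_origin else sm.add_constant(x)
    fit = sm.OLS(y, design).fit()
    if through_origin:
        intercept, slope = 0.0, float(fit.params[0])
        dof = max(n - 1, 1)
    else:
        intercept, slope = float(fit.params[0]), float(fit.params[1])
        dof = max(n - 2, 1)
    resid = np.asarray(fit.resid)
    ss_res = float(resid @ resid)
    see = float(np.sqrt(ss_res / dof))
    rmse = float(np.sqrt(ss_res / n))
    r2 = min(max(float(fit.rsquared), 0.0), 1.0)
    p_value = float(fit.f_pvalue) if n >= (2 if through_origin else 3) else float("nan")
    return RegressionReport(
        slope_b=slope,
        intercept_a=intercept,
        r2=r2,
        see=see,
        rmse=rmse,
        p_value=p_value,
        n=n,
        through_origin=through_origin,
    )


def compare_methods(
    series: Mapping[str, tuple[Sequence[float], Sequence[float]]],
    through_origin: bool = False,
) -> pd.DataFrame:
    """One regression report per k-estimation strategy.

    Parameters
    ----------
    series : mapping of method name -> (estimated LAI, true LAI)
        Each pair must hold at least 2 points.

    Returns
    -------
    pandas.DataFrame
        Columns: method, r2, b, a, see, rmse, p, n (estimated regressed
        on true).
    """
    rows = []
    for method, (estimated, true) in series.items():
        rep = linear_fit(true, estimated, through_origin=through_origin)
        rows.append(
            {
                "method": method,
                "r2": rep.r2,
                "b": rep.slope_b,
                "a": rep.intercept_a,
                "see": rep.see,
                "rmse": rep.rmse,
                "p": rep.p_value,
                "n": rep.n,
            }
        )
    return pd.DataFrame(rows, columns=["method", "r2", "b", "a", "see", "rmse", "p", "n"])


def write_report_csv(report: pd.DataFrame, path: str | Path) -> None:
    """Write a method-comparison table to CSV."""
    report.to_csv(path, index=False)
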