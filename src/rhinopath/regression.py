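"""Ordinary least squares with the summary statistics reported by the study
(R-squared, adjusted R-squared, F, p), shared by the raw-species and
contrast-space analyses.

Through-origin fits (used for standardized-contrast regressions) report the
uncentered R-squared with degrees of freedom (1, n-1); fits with an intercept
report the usual centered R-squared with (1, n-2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .records import ValidationError

__all__ = ["RegressionResult", "ols_fit", "f_pvalue", "adjusted_r2"]


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float | None  # None for a through-origin fit
    r2: float
    r2_adj: float
    f_stat: float
    df: tuple[int, int]
    p_value: float
    n: int

    def as_dict(self) -> dict:
        return {
            "slope": self.slope,
            "intercept": self.intercept,
            "r2": self.r2,
            "r2_adj": self.r2_adj,
            "f_stat": self.f_stat,
            "df_num": self.df[0],
            "df_den": self.df[1],
            "p_value": self.p_value,
            "n": self.n,
        }


def ols_fit(x, y, with_intercept: bool = True) -> RegressionResult:
    """Simple least-squares regression of y on x with F-test summary."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be equal-length 1-d vectors")
    n = x.size
    if n < 3:
        raise ValidationError(f"need at least 3 observations, got {n}")
    if np.ptp(x) == 0:
        raise ValidationError("x is constant: no variation in predictor")
    design = sm.add_constant(x) if with_intercept else x[:, None]
    with np.errstate(divide="ignore"):  # a perfect fit has infinite F
        fit = sm.OLS(y, design).fit()
        slope = float(fit.params[-1])
        intercept = float(fit.params[0]) if with_intercept else None
        df = (1, n - 2) if with_intercept else (1, n - 1)
        r2 = float(fit.rsquared)
        f = float(fit.fvalue)
    # a perfect fit gives an infinite F; its tail probability is 0
    p = float(stats.f.sf(f, *df)) if np.isfinite(f) else 0.0
    return RegressionResult(
        slope=slope,
        intercept=intercept,
        r2=r2,
        r2_adj=float(fit.rsquared_adj),
        f_stat=f,
        df=df,
        p_value=p,
        n=n,
    )


def f_pvalue(f: float, df1: int, df2: int) -> float:
    """Upper-tail probability of the F(df1, df2) distribution."""
    if df1 < 1 or df2 < 1:
        raise ValidationError("degrees of freedom must be positive")
    if f < 0:
        raise ValidationError("F statistic must be >= 0")
    return float(stats.f.sf(f, df1, df2))


def adjusted_r2(r2: float, n: int, n_predictors: int = 1) -> float:
    """1 - (1-R^2)(n-1)/(n-p-1); may be negative (never clamped)."""
    if n <= n_predictors + 1:
        raise ValidationError("degenerate degrees of freedom for adjustment")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - n_predictors - 1)
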