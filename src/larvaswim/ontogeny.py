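"""Ontogenetic regressions of maximum swimming speed.

Simple linear (OLS) regressions of daily mean U_max on age (days
post-hatch), daily mean total length (mm) and daily mean developmental
stage, fitted separately per species. The regression runs on daily
means, not per-fish observations, because lengths and stages are
measured on a daily sample rather than per swum fish; a per-fish mode
exists but is not the standard convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = ["RegressionResult", "fit_linear", "regression_table", "PREDICTORS"]

PREDICTORS = ("dph", "length_mm", "stage")


@dataclass(frozen=True)
class RegressionResult:
    """One fitted line U_max = slope·x + intercept with its inference."""

    predictor: str
    slope: float
    intercept: float
    r_squared: float
    p_value: float  # two-sided test of slope = 0
    n: int

    def equation(self, response: str = "U_max") -> str:
        sign = "+" if self.intercept >= 0 else "−"
        return (
            f"{response} = {self.slope:.2f}*{self.predictor} "
            f"{sign} {abs(self.intercept):.2f}"
        )


def fit_linear(x, y, predictor: str = "x") -> RegressionResult:
    """Ordinary least squares of y on x with slope inference.

    R² = 1 − SS_res/SS_tot; the p-value is the two-sided t-test of the
    slope with n − 2 degrees of freedom. Requires n ≥ 3 and non-constant
    x (a vertical scatter has no defined line).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if len(x) < 3:
        raise ValueError(f"need at least 3 points for a regression, got {len(x)}")
    if np.ptp(x) == 0:
        raise ValueError("x is constant: slope is undefined")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    return RegressionResult(
        predictor=predictor,
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        r_squared=float(model.rsquared),
        p_value=float(model.pvalues[1]),
        n=len(x),
    )


def regression_table(daily_means: pd.DataFrame) -> pd.DataFrame:
    """Fit U_max against every available predictor for every species.

    ``daily_means`` needs columns ``species``, ``u_max`` and any of
    ``dph``, ``length_mm``, ``stage`` (length in millimetres). Returns
    one row per species × predictor with slope, intercept, equation
    string, R², p and n; a species missing a predictor column simply
    omits that row (with a warning).
    """
    import warnings

    required = {"species", "u_max"}
    if missing := required - set(daily_means.columns):
        raise ValueError(f"daily_means is missing columns {sorted(missing)}")

    rows = []
    for species, g in daily_means.groupby("species"):
        for pred in PREDICTORS:
            if pred not in g.columns or g[pred].isna().all():
                warnings.warn(
                    f"species {species!r}: predictor {pred!r} unavailable, cell omitted"
                )
                continue
            sub = g.dropna(subset=[pred, "u_max"])
            res = fit_linear(sub[pred], sub["u_max"], predictor=pred)
            rows.append(
                {
                    "species": species,
                    "predictor": pred,
                    "slope": res.slope,
                    "intercept": res.intercept,
                    "equation": res.equation(),
                    "r_squared": res.r_squared,
                    "p_value": res.p_value,
                    "n": res.n,
                }
            )
    return pd.DataFrame(rows)
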