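"""Linear time trends in indicator series, with AR(1) correction.

Each indicator series is first fit by ordinary least squares on year. If the
residuals show positive serial correlation (Durbin-Watson test, normal
approximation, one-sided at alpha = 0.05), the trend is refit with an AR(1)
error structure by exact maximum likelihood. Significance is declared at
p < 0.05, two-sided, matching the convention of the summary trend tables.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.stattools import durbin_watson as _sm_dw

from .ar1 import fit_ar1_ml

log = logging.getLogger(__name__)

ALPHA = 0.05


@dataclass
class TrendResult:
    slope: float
    intercept: float
    slope_se: float
    p_value: float
    ar1_applied: bool
    rho: float | None
    dw_stat: float
    n: int

    @property
    def significant(self) -> bool:
        return self.p_value < ALPHA


def _design(years: np.ndarray) -> np.ndarray:
    return np.column_stack([np.ones_like(years), years])


def ols_trend(years, values) -> TrendResult:
    """Ordinary least squares of value on year with a two-sided slope t-test."""
    years = np.asarray(years, dtype=float)
    values = np.asarray(values, dtype=float)
    if len(years) < 3:
        raise ValueError("trend fit needs at least 3 years")
    if np.ptp(years) == 0:
        raise ValueError("degenerate design: all years identical")
    fit = fit_ar1_ml(years, values, _design(years), estimate_rho=False)
    resid = values - _design(years) @ fit.beta
    order = np.argsort(years)
    dw = float(_sm_dw(resid[order])) if np.any(resid != 0) else 2.0
    p = fit.t_pvalues()[1]
    if abs(fit.beta[1]) < 1e-12:
        p = 1.0
    return TrendResult(
        slope=float(fit.beta[1]),
        intercept=float(fit.beta[0]),
        slope_se=float(fit.se[1]),
        p_value=float(p),
        ar1_applied=False,
        rho=None,
        dw_stat=dw,
        n=fit.n,
    )


def durbin_watson(residuals) -> tuple[float, bool]:
    """Durbin-Watson statistic and a one-sided positive-autocorrelation flag.

    Uses the large-sample normal approximation z = (1 - DW/2) * sqrt(n); the
    flag is True when z exceeds the upper alpha = 0.05 normal quantile. With
    fewer than 4 residuals the test is uninformative and the flag is False.
    """
    residuals = np.asarray(residuals, dtype=float)
    n = len(residuals)
    if np.all(residuals == 0):
        return 2.0, False
    dw = float(_sm_dw(residuals))
    if n < 4:
        log.warning("Durbin-Watson with n=%d is uninformative; no correction applied", n)
        return dw, False
    z = (1.0 - dw / 2.0) * math.sqrt(n)
    return dw, bool(stats.norm.sf(z) < ALPHA)


def ar1_trend(years, values) -> TrendResult:
    """Trend with AR(1) errors by exact ML; gaps follow rho^|dt| correlation."""
    years = np.asarray(years, dtype=float)
    values = np.asarray(values, dtype=float)
    if len(years) < 5:
        raise ValueError("AR(1) trend fit needs at least 5 years")
    if np.ptp(values) == 0:
        log.warning("constant series; AR(1) trend degenerate, returning zero slope")
        return TrendResult(0.0, float(values[0]), 0.0, 1.0, True, 0.0, 2.0, len(years))
    fit = fit_ar1_ml(years, values, _design(years), estimate_rho=True)
    if not fit.converged:
        log.warning("AR(1) ML did not converge; falling back to OLS")
        return ols_trend(years, values)
    resid = values - _design(years) @ fit.beta
    order = np.argsort(years)
    return TrendResult(
        slope=float(fit.beta[1]),
        intercept=float(fit.beta[0]),
        slope_se=float(fit.se[1]),
        p_value=float(fit.t_pvalues()[1]),
        ar1_applied=True,
        rho=float(fit.rho),
        dw_stat=float(_sm_dw(resid[order])),
        n=fit.n,
    )


def trend_pipeline(years, values) -> TrendResult:
    """OLS trend, AR(1)-corrected when the residuals show serial correlation."""
    years = np.asarray(years, dtype=float)
    values = np.asarray(values, dtype=float)
    order = np.argsort(years)
    res = ols_trend(years[order], values[order])
    resid = values[order] - (res.intercept + res.slope * years[order])
    dw, flagged = durbin_watson(resid)
    if flagged and len(years) >= 5:
        return ar1_trend(years[order], values[order])
    return res


def trend_table(series: pd.DataFrame, columns: list[str], year_col: str = "year") -> pd.DataFrame:
    """Run the trend pipeline over several indicator columns of one series.

    Rows with undefined (NaN) values are dropped per column. Returns one row
    per indicator: n, slope, se, p, ar1_applied, rho, dw, significant.
    """
    rows = []
    for col in columns:
        sub = series[[year_col, col]].dropna()
        if len(sub) < 3:
            log.warning("indicator %s: only %d usable years, skipped", col, len(sub))
            continue
        res = trend_pipeline(sub[year_col].to_numpy(), sub[col].to_numpy())
        rows.append(
            {
                "indicator": col,
                "n": res.n,
                "slope": res.slope,
                "se": res.slope_se,
                "p": res.p_value,
                "ar1_applied": res.ar1_applied,
                "rho": res.rho,
                "dw": res.dw_stat,
                "significant": res.significant,
            }
        )
    return pd.DataFrame(rows)
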