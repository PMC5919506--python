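"""Relative importance of predictors by summed Akaike weights.

For each indicator series, all 2^3 = 8 subsets of {biomass, relative F,
temperature} are fit as generalized least squares models with AR(1) error
correlation (exact ML, so information criteria are comparable). Akaike
weights exp(-delta_i/2)/sum_j exp(-delta_j/2) are summed over the four models
containing each predictor; the predictor with the largest summed weight ranks
first. Model-averaged coefficients are reported both conditionally (averaged
over containing models) and in full (absent models contribute zero).
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ar1 import fit_ar1_ml

log = logging.getLogger(__name__)

PREDICTORS = ["log_biomass", "log_relF", "temperature"]
TIE_TOL = 1e-10


@dataclass(frozen=True)
class ModelSpec:
    predictors: tuple[str, ...]

    def __contains__(self, name: str) -> bool:
        return name in self.predictors

    @property
    def label(self) -> str:
        return " + ".join(self.predictors) if self.predictors else "(intercept only)"


@dataclass
class ModelFit:
    spec: ModelSpec
    intercept: float
    coefficients: dict[str, float]
    rho: float
    loglik: float
    k: int
    n: int
    ic: float = math.nan
    delta: float = math.nan
    weight: float = math.nan


@dataclass
class ImportanceResult:
    summed_weight: dict[str, float]
    rank: dict[str, int]
    averaged_coefficient: dict[str, float]  # conditional average
    full_average: dict[str, float]  # absent models count as zero
    ties: bool
    fits: list[ModelFit] = field(default_factory=list)

    def first_ranked(self) -> list[str]:
        """Predictors sharing rank 1 (more than one under a tie)."""
        return [p for p, r in self.rank.items() if r == 1]


def canonical_model_set() -> list[ModelSpec]:
    """The 8 models: every subset of the three predictors, intercept first."""
    specs = []
    for r in range(len(PREDICTORS) + 1):
        for combo in itertools.combinations(PREDICTORS, r):
            specs.append(ModelSpec(tuple(combo)))
    return specs


def fit_gls_ar1(years, response, table: pd.DataFrame, spec: ModelSpec) -> ModelFit:
    """Fit one model of the set by ML with AR(1)-correlated errors.

    ``k`` counts the intercept, the predictors, rho and the residual
    variance, as required for information-criterion comparison.
    """
    years = np.asarray(years, dtype=float)
    y = np.asarray(response, dtype=float)
    cols = [np.ones(len(y))] + [table[p].to_numpy(dtype=float) for p in spec.predictors]
    X = np.column_stack(cols)
    fit = fit_ar1_ml(years, y, X, estimate_rho=True)
    coefs = {p: float(b) for p, b in zip(spec.predictors, fit.beta[1:])}
    return ModelFit(
        spec=spec,
        intercept=float(fit.beta[0]),
        coefficients=coefs,
        rho=float(fit.rho),
        loglik=float(fit.loglik),
        k=len(spec.predictors) + 3,
        n=fit.n,
    )


def akaike_weights(fits: list[ModelFit], criterion: str = "AIC") -> list[ModelFit]:
    """Attach IC, delta and Akaike weight to each fit (in place, returned).

    ``criterion`` is AIC (default) or AICc, the small-sample correction
    AIC + 2k(k+1)/(n-k-1).
    """
    if len({f.n for f in fits}) != 1:
        raise ValueError("model set fits span different response rows; weights are undefined")
    for f in fits:
        ic = -2.0 * f.loglik + 2.0 * f.k
        if criterion == "AICc":
            denom = f.n - f.k - 1
            if denom <= 0:
                raise ValueError(f"AICc undefined: n={f.n}, k={f.k}")
            ic += 2.0 * f.k * (f.k + 1) / denom
        elif criterion != "AIC":
            raise ValueError(f"unknown criterion {criterion!r}")
        f.ic = ic
    best = min(f.ic for f in fits)
    for f in fits:
        f.delta = f.ic - best
    rel = np.array([math.exp(-0.5 * f.delta) for f in fits])
    w = rel / rel.sum()
    for f, wi in zip(fits, w):
        f.weight = float(wi)
    return fits


def summed_importance(fits: list[ModelFit]) -> ImportanceResult:
    """Summed Akaike weights per predictor, ranks (1 = most important), ties."""
    summed = {
        p: float(sum(f.weight for f in fits if p in f.spec)) for p in PREDICTORS
    }
    order = sorted(PREDICTORS, key=lambda p: -summed[p])
    rank: dict[str, int] = {}
    ties = False
    r = 0
    prev: float | None = None
    for i, p in enumerate(order, start=1):
        if prev is not None and abs(summed[p] - prev) <= TIE_TOL:
            ties = True  # shares the previous rank
        else:
            r = i
        rank[p] = r
        prev = summed[p]

    cond_avg, full_avg = model_average(fits)
    return ImportanceResult(
        summed_weight=summed,
        rank=rank,
        averaged_coefficient=cond_avg,
        full_average=full_avg,
        ties=ties,
        fits=fits,
    )


def model_average(fits: list[ModelFit]) -> tuple[dict[str, float], dict[str, float]]:
    """Model-averaged coefficients per predictor.

    Returns (conditional, full): conditional averages over the models
    containing the predictor, normalized by their total weight; full averages
    treat models without the predictor as contributing a zero coefficient.
    """
    cond_avg: dict[str, float] = {}
    full_avg: dict[str, float] = {}
    for p in PREDICTORS:
        containing = [f for f in fits if p in f.spec]
        wsum = sum(f.weight for f in containing)
        num = sum(f.weight * f.coefficients[p] for f in containing)
        cond_avg[p] = num / wsum if wsum > 0 else math.nan
        full_avg[p] = num
    return cond_avg, full_avg


def importance_for_series(
    years, response, table: pd.DataFrame, criterion: str = "AIC"
) -> ImportanceResult:
    """Fit the 8-model set on one indicator series and summarize importance."""
    fits = [fit_gls_ar1(years, response, table, spec) for spec in canonical_model_set()]
    return summed_importance(akaike_weights(fits, criterion))


def importance_pipeline(
    indicator_table: pd.DataFrame,
    predictor_table: pd.DataFrame,
    indicators: list[str] | None = None,
    criterion: str = "AIC",
    min_rows: int = 8,
) -> dict[str, ImportanceResult]:
    """Importance analysis for each indicator of one stock x season.

    Indicator and predictor tables are aligned on year; indicators with fewer
    than ``min_rows`` usable years are skipped with a warning.
    """
    from .indicators import INDICATOR_NAMES

    indicators = indicators or INDICATOR_NAMES
    merged = indicator_table.merge(predictor_table, on="year", how="inner")
    out: dict[str, ImportanceResult] = {}
    for ind in indicators:
        sub = merged[["year", ind, *PREDICTORS]].dropna()
        if len(sub) < min_rows:
            log.warning("indicator %s: %d aligned years < %d required, skipped", ind, len(sub), min_rows)
            continue
        out[ind] = importance_for_series(
            sub["year"].to_numpy(), sub[ind].to_numpy(), sub, criterion
        )
    return out


def first_rank_proportions(results_by_stock: dict[str, dict[str, ImportanceResult]]) -> pd.DataFrame:
    """Cross-stock summary: proportion of stocks where each predictor ranks first.

    Tied predictors are each counted, so per-indicator proportions may sum to
    more than one.
    """
    rows = []
    indicators = sorted({ind for res in results_by_stock.values() for ind in res})
    for ind in indicators:
        stocks_with = [s for s, res in results_by_stock.items() if ind in res]
        for p in PREDICTORS:
            n_first = sum(1 for s in stocks_with if p in results_by_stock[s][ind].first_ranked())
            rows.append(
                {
                    "indicator": ind,
                    "predictor": p,
                    "n_stocks": len(stocks_with),
                    "n_first": n_first,
                    "proportion_first": n_first / len(stocks_with) if stocks_with else math.nan,
                }
            )
    return pd.DataFrame(rows)
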