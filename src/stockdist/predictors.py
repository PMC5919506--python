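"""Predictor series for the variable-importance analysis.

Three annual predictors are built per stock and season from the survey and
catch data: the design-based stratified mean biomass (kg per tow) as a
relative population-size index; relative F (catch divided by the biomass
index) as a fishing-pressure index; and the stratified mean bottom
temperature. Biomass and relative F are log transformed. Year filters: years
in which not all strata were sampled are omitted everywhere, and years with
insufficient temperature coverage (or no catch) are additionally omitted from
the importance analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stocks import SeasonStrata, StockDefinition, select_survey


@dataclass(frozen=True)
class StratifiedMean:
    year: int
    value: float  # kg per tow, or degC; NaN when no stratum has data
    n_strata_used: int
    coverage_fraction: float  # area of strata with data / total stock strata area


def stratified_mean(values_by_stratum: dict[str, np.ndarray], strata: SeasonStrata, year: int = 0) -> StratifiedMean:
    """Design-based stratified mean: sum_h (A_h / A_total) * mean_h.

    ``A_total`` is the total stock strata area, including strata without
    data, so incomplete coverage shrinks the estimate toward zero;
    ``coverage_fraction`` reports the covered area share.
    """
    a_total = strata.total_area
    num = 0.0
    covered = 0.0
    n_used = 0
    for sid, area in strata.areas.items():
        vals = np.asarray(values_by_stratum.get(sid, []), dtype=float)
        vals = vals[~np.isnan(vals)]
        if vals.size:
            num += area * vals.mean()
            covered += area
            n_used += 1
    if n_used == 0:
        return StratifiedMean(year, math.nan, 0, 0.0)
    return StratifiedMean(year, num / a_total, n_used, covered / a_total)


def survey_stratified_mean(
    survey: pd.DataFrame, stock: StockDefinition, season: str, column: str
) -> pd.DataFrame:
    """Annual stratified means of one survey column for a stock x season.

    Returns a DataFrame with year, value, n_strata_used, coverage_fraction.
    """
    strata = stock.season_strata(season)
    sub = select_survey(survey, stock, season)
    rows = []
    for yr, grp in sub.groupby("year"):
        by_stratum = {sid: g[column].to_numpy() for sid, g in grp.groupby("stratum")}
        sm = stratified_mean(by_stratum, strata, year=int(yr))
        rows.append(sm.__dict__)
    return pd.DataFrame(rows).sort_values("year").reset_index(drop=True)


def relative_f(catch: float, biomass_index: float) -> float:
    """Exploitation-rate proxy: annual catch / stratified mean kg per tow."""
    if catch is None or math.isnan(catch) or math.isnan(biomass_index) or biomass_index <= 0:
        return math.nan
    return catch / biomass_index


def filter_complete_years(survey: pd.DataFrame, stock: StockDefinition, season: str) -> set[int]:
    """Years in which every stratum of the stock definition has >= 1 station."""
    strata = stock.season_strata(season)
    required = set(strata.polygons)
    sub = select_survey(survey, stock, season)
    out = set()
    for yr, grp in sub.groupby("year"):
        if required <= set(grp["stratum"].unique()):
            out.add(int(yr))
    return out


def filter_temperature_years(
    survey: pd.DataFrame, stock: StockDefinition, season: str, min_coverage: float = 1.0
) -> set[int]:
    """Years whose bottom-temperature stratified mean covers enough strata area.

    The default ``min_coverage=1.0`` requires a temperature record in every
    stratum, mirroring the complete-strata filter.
    """
    if not 0 < min_coverage <= 1:
        raise ValueError("min_coverage must be in (0, 1]")
    temps = survey_stratified_mean(survey, stock, season, "bottom_temp_c")
    # coverage comparison needs a tolerance: area ratios are float arithmetic
    ok = temps["coverage_fraction"] >= min_coverage - 1e-12
    return set(temps.loc[ok, "year"].astype(int))


def build_predictor_table(
    survey: pd.DataFrame,
    stock: StockDefinition,
    season: str,
    min_temp_coverage: float = 1.0,
    log_offset: float = 0.0,
) -> pd.DataFrame:
    """Annual table of log biomass, log relative F and temperature.

    Applies the complete-strata and temperature-coverage filters, requires a
    catch value for the year, and drops years where any component is missing
    or a log argument is non-positive. ``log_offset`` (default 0, i.e. none)
    is added inside both logs when set.
    """
    years = filter_complete_years(survey, stock, season) & filter_temperature_years(
        survey, stock, season, min_temp_coverage
    )
    biomass = survey_stratified_mean(survey, stock, season, stock.name).set_index("year")["value"]
    temperature = survey_stratified_mean(survey, stock, season, "bottom_temp_c").set_index("year")[
        "value"
    ]
    rows = []
    for yr in sorted(years):
        b = biomass.get(yr, math.nan)
        t = temperature.get(yr, math.nan)
        c = stock.catch.get(yr, math.nan)
        rf = relative_f(c, b)
        if math.isnan(b) or math.isnan(t) or math.isnan(rf):
            continue
        if b + log_offset <= 0 or rf + log_offset <= 0:
            continue
        rows.append(
            {
                "year": yr,
                "log_biomass": math.log(b + log_offset),
                "log_relF": math.log(rf + log_offset),
                "temperature": t,
            }
        )
    return pd.DataFrame(rows, columns=["year", "log_biomass", "log_relF", "temperature"])
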