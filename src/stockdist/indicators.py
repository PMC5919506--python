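"""Spatial distribution indicators for one stock, season and year.

Four design-weighted indicators summarize a stock's distribution from the
survey stations: the center of gravity (CG), the biomass-weighted bivariate
mean location; the inertia, the biomass-weighted variance of location around
the CG, decomposed into orthogonal maximum/minimum axes; the biomass-weighted
mean depth; and the positive area, the summed area of influence of stations
with strictly positive biomass. All use station weights w_i (areas of
influence) times biomass z_i; the sample-location CG (z_i = 1) checks that
distribution trends are not artifacts of the sampling design.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geo import to_xy
from .influence import dissolve_boundary, voronoi_weights
from .stocks import StockDefinition, select_survey

log = logging.getLogger(__name__)

INDICATOR_NAMES = ["xcg", "ycg", "inertia", "depth_cg", "positive_area"]


@dataclass
class AnnualIndicators:
    year: int
    xcg: float
    ycg: float
    inertia: float
    axis_max_sd: float
    axis_min_sd: float
    axis_max_bearing: float
    depth_cg: float
    positive_area: float
    sample_xcg: float
    sample_ycg: float
    n_stations: int
    defined: bool


def _mass(w, z):
    w = np.asarray(w, dtype=float)
    z = np.asarray(z, dtype=float)
    return w * z


def center_of_gravity(x, y, w, z) -> tuple[float, float]:
    """Biomass-weighted mean location; NaN pair when total mass is zero."""
    m = _mass(w, z)
    tot = m.sum()
    if tot <= 0:
        return (math.nan, math.nan)
    return float(np.dot(m, x) / tot), float(np.dot(m, y) / tot)


def inertia(x, y, w, z, cg: tuple[float, float]) -> tuple[float, float, float, float]:
    """Weighted variance of location around the CG and its axis decomposition.

    Returns ``(inertia_km2, axis_max_sd, axis_min_sd, axis_max_bearing)``.
    The inertia is the trace of the weighted covariance of (x, y); the axis
    standard deviations are square roots of its eigenvalues and the bearing is
    the principal axis angle in [0, pi) counter-clockwise from east.
    """
    m = _mass(w, z)
    tot = m.sum()
    if tot <= 0:
        return (math.nan,) * 4
    dx = np.asarray(x, dtype=float) - cg[0]
    dy = np.asarray(y, dtype=float) - cg[1]
    cxx = np.dot(m, dx * dx) / tot
    cyy = np.dot(m, dy * dy) / tot
    cxy = np.dot(m, dx * dy) / tot
    cov = np.array([[cxx, cxy], [cxy, cyy]])
    evals, evecs = np.linalg.eigh(cov)
    evals = np.clip(evals, 0.0, None)
    vmax = evecs[:, 1]
    bearing = math.atan2(vmax[1], vmax[0]) % math.pi
    return float(cxx + cyy), float(np.sqrt(evals[1])), float(np.sqrt(evals[0])), float(bearing)


def weighted_depth(depth, w, z) -> float:
    """Biomass-weighted mean depth (m)."""
    m = _mass(w, z)
    tot = m.sum()
    if tot <= 0:
        return math.nan
    return float(np.dot(m, np.asarray(depth, dtype=float)) / tot)


def positive_area(w, z) -> float:
    """Summed area of influence over stations with strictly positive biomass."""
    w = np.asarray(w, dtype=float)
    z = np.asarray(z, dtype=float)
    return float(w[z > 0].sum())


def sample_location_cg(x, y, w) -> tuple[float, float]:
    """CG of the sample locations themselves (z_i = 1): design check."""
    w = np.asarray(w, dtype=float)
    tot = w.sum()
    if tot <= 0:
        raise ValueError("sample_location_cg needs at least one positive weight")
    return float(np.dot(w, x) / tot), float(np.dot(w, y) / tot)


def annual_indicators(x, y, w, z, depth, year: int) -> AnnualIndicators:
    """All indicators for one year of referenced, weighted stations."""
    cg = center_of_gravity(x, y, w, z)
    defined = not math.isnan(cg[0])
    inr, sd_max, sd_min, bearing = inertia(x, y, w, z, cg)
    sx, sy = sample_location_cg(x, y, w)
    if not defined:
        log.info("year %d: total weighted biomass is zero; CG-based indicators undefined", year)
    return AnnualIndicators(
        year=int(year),
        xcg=cg[0],
        ycg=cg[1],
        inertia=inr,
        axis_max_sd=sd_max,
        axis_min_sd=sd_min,
        axis_max_bearing=bearing,
        depth_cg=weighted_depth(depth, w, z),
        positive_area=positive_area(w, z),
        sample_xcg=sx,
        sample_ycg=sy,
        n_stations=len(np.asarray(w)),
        defined=defined,
    )


def annual_series(
    survey: pd.DataFrame,
    stock: StockDefinition,
    season: str,
    require_complete: bool = True,
) -> pd.DataFrame:
    """Indicator table for one stock x season, one row per surveyed year.

    Builds the stock's km frame once, computes Voronoi areas of influence on
    each year's stations, and evaluates all indicators. With
    ``require_complete`` (default), years in which not every stratum of the
    stock definition was sampled are omitted.
    """
    from .predictors import filter_complete_years  # local import avoids a cycle

    strata = stock.season_strata(season)
    frame = strata.frame()
    boundary = dissolve_boundary(strata.km_strata(frame))
    sub = select_survey(survey, stock, season)
    years = sorted(sub["year"].unique())
    if require_complete:
        keep = filter_complete_years(survey, stock, season)
        years = [yr for yr in years if yr in keep]
    rows = []
    for yr in years:
        st = sub[sub["year"] == yr]
        if st.empty:
            continue
        x, y = to_xy(st["lon"].to_numpy(), st["lat"].to_numpy(), frame)
        infl = voronoi_weights(x, y, boundary)
        ok = infl.weights > 0
        ann = annual_indicators(
            x[ok],
            y[ok],
            infl.weights[ok],
            st[stock.name].to_numpy()[ok],
            st["depth_m"].to_numpy()[ok],
            yr,
        )
        rows.append(ann.__dict__)
    return pd.DataFrame(rows)
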