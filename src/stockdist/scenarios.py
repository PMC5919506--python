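"""Canonical simulation scenarios used to validate every pipeline stage.

Each scenario is a fixed study condition: its parameters define the data-
generating process against which the estimators are checked, and are not
tuning knobs. The runners execute the full pipeline (simulate -> reference ->
tessellate -> indicators -> trend / importance) and report the estimate
against the planted truth.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .indicators import annual_series
from .importance import importance_pipeline
from .predictors import build_predictor_table
from .simulate import ScenarioConfig, make_stock, simulate_scenario, simulate_survey
from .trends import trend_pipeline


def trend_recovery_scenario() -> ScenarioConfig:
    """Northward drift of 1 km/yr over 50 survey years (generator defaults)."""
    return ScenarioConfig()


def planted_relf_scenario() -> ScenarioConfig:
    """Fishing pressure drives the east-west CG; temperature anomaly flat.

    A strongly persistent exogenous relative-F series displaces the next
    year's true XCG by 50 km per unit log relative F anomaly; sampling is
    doubled so the indicator noise does not mask the planted driver.
    """
    return ScenarioConfig(
        n_years=40,
        cg_trend=(0.0, 0.0),
        beta_relF_x=50.0,
        log_relF_rho=0.95,
        stations_per_km2=0.003,
        temp_anomaly_sd=0.0,
    )


def null_relf_scenario() -> ScenarioConfig:
    """No fishing-pressure signal: relative F constant, no planted effect."""
    return ScenarioConfig(
        n_years=40,
        cg_trend=(0.0, 0.0),
        beta_relF_x=0.0,
        log_relF_sd=0.0,
        stations_per_km2=0.003,
        temp_anomaly_sd=0.0,
    )


def stationary_design_scenario() -> ScenarioConfig:
    """Stationary population and sampling design, 20 years (design check)."""
    return ScenarioConfig(n_years=20, cg_trend=(0.0, 0.0))


def estimate_ycg_trend(seed: int, config: ScenarioConfig | None = None):
    """Full-pipeline YCG trend for one realization.

    Returns ``(slope, ci_low, ci_high)`` with a 95% t confidence interval
    from the (possibly AR(1)-corrected) trend fit.
    """
    config = config or trend_recovery_scenario()
    survey, _ = simulate_survey(config, seed)
    ind = annual_series(survey, make_stock(config), config.seasons[0])
    sub = ind[["year", "ycg"]].dropna()
    res = trend_pipeline(sub["year"].to_numpy(), sub["ycg"].to_numpy())
    tcrit = stats.t.ppf(0.975, res.n - 2)
    return res.slope, res.slope - tcrit * res.slope_se, res.slope + tcrit * res.slope_se


def xcg_relf_ranked_first(seed: int, config: ScenarioConfig) -> bool:
    """Does the importance analysis rank relative F first for XCG?"""
    survey, stock, _ = simulate_scenario(config, seed)
    season = config.seasons[0]
    ind = annual_series(survey, stock, season)
    pred = build_predictor_table(survey, stock, season)
    res = importance_pipeline(ind, pred, indicators=["xcg"])
    if "xcg" not in res:
        return False
    return "log_relF" in res["xcg"].first_ranked()


def sample_cg_trend_significant(seed: int, config: ScenarioConfig | None = None):
    """Significance of the sample-location CG trends (x, y) for one run."""
    config = config or stationary_design_scenario()
    survey, _ = simulate_survey(config, seed)
    ind = annual_series(survey, make_stock(config), config.seasons[0])
    out = []
    for col in ("sample_xcg", "sample_ycg"):
        res = trend_pipeline(ind["year"].to_numpy(), ind[col].to_numpy())
        out.append(res.significant)
    return tuple(out)


def random_voronoi_instance(rng: np.random.Generator):
    """One random tessellation instance: (x, y, boundary)."""
    from shapely.geometry import box
    from shapely.ops import unary_union

    if rng.uniform() < 0.5:
        w, h = rng.uniform(40, 150, 2)
        boundary = box(0, 0, w, h)
    else:
        s = rng.uniform(60, 150)
        boundary = unary_union([box(0, 0, s, s / 2), box(0, 0, s / 2, s)])
    n = int(rng.integers(3, 101))
    minx, miny, maxx, maxy = boundary.bounds
    pts = []
    while len(pts) < n:
        p = rng.uniform((minx, miny), (maxx, maxy))
        from shapely import contains_xy

        if contains_xy(boundary, p[0], p[1]):
            pts.append(p)
    pts = np.array(pts)
    return pts[:, 0], pts[:, 1], boundary
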