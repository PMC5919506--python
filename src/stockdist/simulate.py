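"""Synthetic stratified-random trawl survey with known distribution dynamics.

Emulates the statistical structure the pipeline assumes: stations allocated
to rectangular strata proportionally to area (largest-remainder rounding,
floor of two per stratum so within-stratum means stay defined) and placed
uniformly within each stratum; a biomass surface with an isotropic
Gaussian-decay mean around a true center of gravity that drifts linearly in
time (optionally displaced by the previous year's fishing pressure);
zero-inflated log-normal biomass whose occupancy probability decays with
distance from the center, so positive area co-varies with concentration; a
bottom-temperature field with a north-south gradient plus an interannual
anomaly; a planar depth field; and a catch series equal to an exogenous
relative-F series times the realized survey biomass index, so the fitted
log relative F recovers the exogenous series exactly.

Every quantity the downstream stages estimate (CG path and trend, nominal
inertia, expected positive area, planted predictor coefficients) is exposed
as ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import box

from .geo import KM_PER_DEGREE, ReferenceFrame, polygon_from_xy
from .predictors import survey_stratified_mean
from .stocks import SeasonStrata, StockDefinition


@dataclass
class ScenarioConfig:
    """Study conditions for one synthetic stock.

    Defaults mirror the scale of the groundfish survey application: ~50
    survey years, a 150x150 km stock area of nine equal-area strata, a
    station density giving ~35 stations per year, a northward center-of-
    gravity drift of 1 km/yr, and a biomass plume with nominal inertia
    450 km^2 (15 km per-axis standard deviation).
    """

    n_years: int = 50
    start_year: int = 1968
    seasons: tuple[str, ...] = ("SPRING",)
    grid_rows: int = 3
    grid_cols: int = 3
    cell_km: float = 50.0
    stations_per_km2: float = 0.0015
    cg_start: tuple[float, float] = (75.0, 40.0)
    cg_trend: tuple[float, float] = (0.0, 1.0)  # km/yr
    inertia_target: float = 450.0  # km^2 -> per-axis sd sqrt(target/2)
    zero_inflation: float = 0.3  # zero probability at the plume center is 1-(1-zi)
    occupancy_scale: float = 30.0  # km; distance scale of occupancy decay
    mean_density: float = 20.0  # kg/tow at the plume center
    lognormal_sd: float = 0.6  # sd of log biomass given occupancy
    log_abundance_sd: float = 0.15  # interannual sd of log total abundance
    log_abundance_rho: float = 0.5
    depth0: float = 50.0  # m at the frame origin
    depth_gradient: tuple[float, float] = (0.3, 1.0)  # m/km east, north
    depth_noise_sd: float = 5.0
    temp0: float = 8.0  # degC at the origin
    temp_gradient: float = -0.02  # degC per km north
    temp_anomaly_sd: float = 0.5  # interannual anomaly (degC)
    temp_noise_sd: float = 0.3  # within-year station noise (degC)
    relF_mean: float = 0.5  # exogenous relative-F level
    log_relF_sd: float = 0.4
    log_relF_rho: float = 0.8
    beta_relF_x: float = 0.0  # km shift of next year's true XCG per unit log relF anomaly
    origin_lon: float = -70.0
    origin_lat: float = 40.0
    stock_name: str = "SYNTH"

    @property
    def plume_sd(self) -> float:
        return math.sqrt(self.inertia_target / 2.0)

    @property
    def width_km(self) -> float:
        return self.grid_cols * self.cell_km

    @property
    def height_km(self) -> float:
        return self.grid_rows * self.cell_km

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.start_year, self.start_year + self.n_years)

    def frame(self) -> ReferenceFrame:
        lat_max = self.origin_lat + self.height_km / KM_PER_DEGREE
        return ReferenceFrame(
            self.origin_lon, self.origin_lat, 0.5 * (self.origin_lat + lat_max)
        )


@dataclass
class GroundTruth:
    config: ScenarioConfig
    cg_path: pd.DataFrame  # year, true_xcg, true_ycg (km frame)
    log_relF: pd.Series  # year -> exogenous log relative F
    log_abundance: pd.Series  # year -> log abundance multiplier
    temp_anomaly: pd.Series  # year -> interannual anomaly (degC)
    expected_pa: pd.Series = field(default=None)  # year -> E[positive area] km^2

    @property
    def cg_trend(self) -> tuple[float, float]:
        return self.config.cg_trend

    @property
    def inertia_nominal(self) -> float:
        return self.config.inertia_target


def allocate_stations(areas: np.ndarray, density: float, floor: int = 2) -> np.ndarray:
    """Largest-remainder proportional allocation with a per-stratum floor."""
    raw = areas * density
    base = np.floor(raw).astype(int)
    remainder = int(round(raw.sum())) - base.sum()
    if remainder > 0:
        order = np.argsort(-(raw - base))
        base[order[:remainder]] += 1
    return np.maximum(base, floor)


def make_strata(config: ScenarioConfig) -> SeasonStrata:
    """Non-overlapping rectangular strata tiling the stock area (lon/lat)."""
    frame = config.frame()
    polygons = {}
    areas = {}
    for r in range(config.grid_rows):
        for c in range(config.grid_cols):
            sid = f"S{r * config.grid_cols + c + 1:02d}"
            km_box = box(
                c * config.cell_km,
                r * config.cell_km,
                (c + 1) * config.cell_km,
                (r + 1) * config.cell_km,
            )
            polygons[sid] = polygon_from_xy(km_box, frame)
            areas[sid] = config.cell_km**2
    return SeasonStrata(polygons=polygons, areas=areas)


def _true_cg_path(config: ScenarioConfig, log_relF: np.ndarray) -> pd.DataFrame:
    yrs = config.years
    t = yrs - yrs[0]
    x = config.cg_start[0] + config.cg_trend[0] * t
    y = config.cg_start[1] + config.cg_trend[1] * t
    if config.beta_relF_x != 0.0:
        anom = log_relF - math.log(config.relF_mean)
        # fishing pressure displaces the following year's center east-west
        x = x + config.beta_relF_x * np.concatenate([[0.0], anom[:-1]])
    return pd.DataFrame({"year": yrs, "true_xcg": x, "true_ycg": y})


def _ar1_series(rng: np.random.Generator, n: int, rho: float, sd: float) -> np.ndarray:
    innov_sd = sd * math.sqrt(max(1.0 - rho**2, 1e-12))
    out = np.empty(n)
    out[0] = rng.normal(0.0, sd)
    for i in range(1, n):
        out[i] = rho * out[i - 1] + rng.normal(0.0, innov_sd)
    return out


def zero_probability(config: ScenarioConfig, dist: np.ndarray) -> np.ndarray:
    """P(z = 0) at distance ``dist`` from the true CG.

    ``(1 - zi)^(1 + (d/scale)^2)``: exactly 0 when zero_inflation is 0,
    exactly 1 when it is 1, and increasing with distance otherwise.
    """
    zi = config.zero_inflation
    if zi <= 0.0:
        return np.zeros_like(dist)
    if zi >= 1.0:
        return np.ones_like(dist)
    expo = 1.0 + (dist / config.occupancy_scale) ** 2
    return 1.0 - (1.0 - zi) ** expo


def expected_positive_area(config: ScenarioConfig, cg: tuple[float, float], n_grid: int = 120) -> float:
    """E[positive area] for one year: integral of P(z > 0) over the stock area."""
    xs = np.linspace(0, config.width_km, n_grid, endpoint=False) + config.width_km / n_grid / 2
    ys = np.linspace(0, config.height_km, n_grid, endpoint=False) + config.height_km / n_grid / 2
    gx, gy = np.meshgrid(xs, ys)
    d = np.hypot(gx - cg[0], gy - cg[1])
    p_pos = 1.0 - zero_probability(config, d)
    cell = (config.width_km / n_grid) * (config.height_km / n_grid)
    return float(p_pos.sum() * cell)


def simulate_survey(config: ScenarioConfig, seed: int) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate the survey table for all years and seasons of the scenario.

    Returns the canonical survey DataFrame and the scenario's ground truth.
    Bit-reproducible for a fixed (config, seed).
    """
    rng = np.random.default_rng(seed)
    frame = config.frame()
    strata = make_strata(config)
    sids = list(strata.polygons)
    areas = np.array([strata.areas[s] for s in sids])
    counts = allocate_stations(areas, config.stations_per_km2)
    # stratum km bounding boxes (grid construction: row-major rectangles)
    km_bounds = []
    for r in range(config.grid_rows):
        for c in range(config.grid_cols):
            km_bounds.append(
                (c * config.cell_km, r * config.cell_km, (c + 1) * config.cell_km, (r + 1) * config.cell_km)
            )

    n = config.n_years
    log_relF = math.log(config.relF_mean) + _ar1_series(rng, n, config.log_relF_rho, config.log_relF_sd)
    log_abund = _ar1_series(rng, n, config.log_abundance_rho, config.log_abundance_sd)
    temp_anom = rng.normal(0.0, config.temp_anomaly_sd, size=n)
    cg_path = _true_cg_path(config, log_relF)

    sd = config.plume_sd
    records = []
    for iy, yr in enumerate(config.years):
        cgx = cg_path["true_xcg"].iloc[iy]
        cgy = cg_path["true_ycg"].iloc[iy]
        amp = config.mean_density * math.exp(log_abund[iy])
        for season in config.seasons:
            for sid, (x0, y0, x1, y1), m in zip(sids, km_bounds, counts):
                x = rng.uniform(x0, x1, size=m)
                y = rng.uniform(y0, y1, size=m)
                d = np.hypot(x - cgx, y - cgy)
                mu = amp * np.exp(-0.5 * (d / sd) ** 2)
                occupied = rng.uniform(size=m) >= zero_probability(config, d)
                logz = rng.normal(
                    np.log(np.maximum(mu, 1e-300)) - 0.5 * config.lognormal_sd**2,
                    config.lognormal_sd,
                )
                z = np.where(occupied, np.exp(logz), 0.0)
                depth = np.maximum(
                    config.depth0
                    + config.depth_gradient[0] * x
                    + config.depth_gradient[1] * y
                    + rng.normal(0.0, config.depth_noise_sd, size=m),
                    5.0,
                )
                temp = (
                    config.temp0
                    + config.temp_gradient * y
                    + temp_anom[iy]
                    + rng.normal(0.0, config.temp_noise_sd, size=m)
                )
                lon = frame.origin_lon + x / (frame.km_per_degree * frame.cos_mid)
                lat = frame.origin_lat + y / frame.km_per_degree
                for j in range(m):
                    records.append(
                        (int(yr), season, sid, lon[j], lat[j], depth[j], temp[j], z[j])
                    )
    survey = pd.DataFrame(
        records,
        columns=["year", "season", "stratum", "lon", "lat", "depth_m", "bottom_temp_c", config.stock_name],
    )
    yrs = config.years
    truth = GroundTruth(
        config=config,
        cg_path=cg_path,
        log_relF=pd.Series(log_relF, index=yrs),
        log_abundance=pd.Series(log_abund, index=yrs),
        temp_anomaly=pd.Series(temp_anom, index=yrs),
        expected_pa=pd.Series(
            [
                expected_positive_area(config, (cg_path["true_xcg"].iloc[i], cg_path["true_ycg"].iloc[i]))
                for i in range(n)
            ],
            index=yrs,
        ),
    )
    return survey, truth


def simulate_catch(
    config: ScenarioConfig,
    seed: int,
    survey: pd.DataFrame | None = None,
    truth: GroundTruth | None = None,
) -> pd.Series:
    """Annual catch: exogenous relative F times the realized biomass index.

    With the survey of the same (config, seed), catch / stratified-mean-kg-
    per-tow reproduces the exogenous relative-F series exactly, giving the
    importance stage a predictor with known dynamics. The index comes from
    the first configured season.
    """
    if survey is None or truth is None:
        survey, truth = simulate_survey(config, seed)
    stock = StockDefinition(
        name=config.stock_name, strata={s: make_strata(config) for s in config.seasons}
    )
    index = survey_stratified_mean(survey, stock, config.seasons[0], config.stock_name)
    index = index.set_index("year")["value"]
    relF = np.exp(truth.log_relF)
    return (relF * index).rename("catch").dropna()


def make_stock(config: ScenarioConfig, catch: pd.Series | None = None) -> StockDefinition:
    """StockDefinition matching the scenario's strata (all seasons) and catch."""
    strata = {s: make_strata(config) for s in config.seasons}
    return StockDefinition(
        name=config.stock_name,
        strata=strata,
        catch=catch if catch is not None else pd.Series(dtype=float),
    )


def simulate_scenario(
    config: ScenarioConfig, seed: int
) -> tuple[pd.DataFrame, StockDefinition, GroundTruth]:
    """Survey + stock definition (with catch) + ground truth in one call."""
    survey, truth = simulate_survey(config, seed)
    catch = simulate_catch(config, seed, survey, truth)
    return survey, make_stock(config, catch), truth
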