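"""Readers, writers and pipeline drivers tying the stages together.

Formats
-------
Survey CSV: canonical columns ``year, season, stratum, lon, lat, depth_m,
bottom_temp_c`` plus one biomass column (kg per tow) per stock; comma
separated, UTF-8, mandatory header, empty fields for missing values, seasons
as uppercase tokens, 4-digit years. A column-mapping dict adapts externally
deposited files. Catch CSV: ``stock, year, catch``. Strata JSON: per stock,
per season, a mapping from stratum id to a WKT polygon (lon/lat) and its
area in km^2.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import pandas as pd
from shapely import wkt as shapely_wkt

from .indicators import INDICATOR_NAMES, annual_series
from .importance import PREDICTORS, first_rank_proportions, importance_pipeline
from .predictors import build_predictor_table
from .simulate import ScenarioConfig, make_stock, simulate_catch, simulate_survey
from .stocks import SURVEY_COLUMNS, SeasonStrata, StockDefinition
from .trends import trend_table

log = logging.getLogger(__name__)


@dataclasses.dataclass
class RunConfig:
    survey_csv: str | None = None
    catch_csv: str | None = None
    strata_json: str | None = None
    out_dir: str = "results"
    stocks: list[str] | None = None  # None = all stocks in the strata file
    seasons: list[str] | None = None
    min_temp_coverage: float = 1.0
    criterion: str = "AIC"
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


def _file_hash(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:12]


def read_survey_csv(path: str | Path, column_map: dict[str, str] | None = None) -> pd.DataFrame:
    """Read a survey CSV, optionally renaming columns via ``column_map``."""
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=column_map)
    missing = [c for c in SURVEY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required survey columns {missing}")
    try:
        df["year"] = df["year"].astype(int)
    except (TypeError, ValueError) as exc:
        bad = df.index[pd.to_numeric(df["year"], errors="coerce").isna()]
        line = int(bad[0]) + 2 if len(bad) else "?"
        raise ValueError(f"{path}: non-integer year near line {line}") from exc
    df["season"] = df["season"].astype(str).str.upper()
    df["stratum"] = df["stratum"].astype(str)
    log.info("survey %s: %d stations, sha256 %s", path, len(df), _file_hash(path))
    return df


def read_catch_csv(path: str | Path, column_map: dict[str, str] | None = None) -> dict[str, pd.Series]:
    """Read a catch CSV into per-stock annual series (year-indexed)."""
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=column_map)
    missing = [c for c in ("stock", "year", "catch") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required catch columns {missing}")
    out = {}
    for stock, grp in df.groupby("stock"):
        s = grp.set_index(grp["year"].astype(int))["catch"].astype(float).sort_index()
        out[str(stock)] = s
    log.info("catch %s: %d stocks, sha256 %s", path, len(out), _file_hash(path))
    return out


def read_strata_json(path: str | Path, catch: dict[str, pd.Series] | None = None) -> dict[str, StockDefinition]:
    """Read stock definitions (per-season strata WKT polygons + areas)."""
    spec = json.loads(Path(path).read_text())
    stocks = {}
    for name, seasons in spec.items():
        strata = {}
        for season, entries in seasons.items():
            polys, areas = {}, {}
            for sid, entry in entries.items():
                polys[sid] = shapely_wkt.loads(entry["wkt"])
                areas[sid] = float(entry["area_km2"])
            strata[season.upper()] = SeasonStrata(polygons=polys, areas=areas)
        c = (catch or {}).get(name, pd.Series(dtype=float))
        stocks[name] = StockDefinition(name=name, strata=strata, catch=c)
    return stocks


def write_strata_json(path: str | Path, stocks: dict[str, StockDefinition]) -> None:
    out = {
        name: {
            season: {
                sid: {"wkt": poly.wkt, "area_km2": ss.areas[sid]}
                for sid, poly in ss.polygons.items()
            }
            for season, ss in stock.strata.items()
        }
        for name, stock in stocks.items()
    }
    Path(path).write_text(json.dumps(out, indent=1))


# ---------------------------------------------------------------- drivers


def _iter_stock_seasons(stocks: dict[str, StockDefinition], cfg: RunConfig):
    for name, stock in stocks.items():
        if cfg.stocks and name not in cfg.stocks:
            continue
        for season in stock.strata:
            if cfg.seasons and season not in cfg.seasons:
                continue
            yield name, stock, season


def run_indicators(survey: pd.DataFrame, stocks: dict[str, StockDefinition], cfg: RunConfig) -> pd.DataFrame:
    """Annual indicator table for every selected stock x season."""
    tables = []
    for name, stock, season in _iter_stock_seasons(stocks, cfg):
        tab = annual_series(survey, stock, season)
        if tab.empty:
            log.warning("%s %s: no usable years", name, season)
            continue
        tab.insert(0, "stock", name)
        tab.insert(1, "season", season)
        tables.append(tab)
    if not tables:
        return pd.DataFrame()
    return pd.concat(tables, ignore_index=True)


TREND_COLUMNS = INDICATOR_NAMES + ["sample_xcg", "sample_ycg"]


def run_trends(indicator_table: pd.DataFrame, significant_only: bool = False) -> pd.DataFrame:
    """Trend table over all indicator series, including the design check."""
    rows = []
    for (name, season), grp in indicator_table.groupby(["stock", "season"]):
        tab = trend_table(grp, TREND_COLUMNS)
        if tab.empty:
            continue
        tab.insert(0, "stock", name)
        tab.insert(1, "season", season)
        rows.append(tab)
    out = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame()
    if significant_only and not out.empty:
        out = out[out["significant"]].reset_index(drop=True)
    return out


def run_importance(
    survey: pd.DataFrame,
    stocks: dict[str, StockDefinition],
    indicator_table: pd.DataFrame,
    cfg: RunConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Importance analysis per stock x season x indicator.

    Returns (model table, importance table, first-rank summary).
    """
    model_rows, importance_rows = [], []
    by_key: dict[str, dict] = {}
    for name, stock, season in _iter_stock_seasons(stocks, cfg):
        pred = build_predictor_table(survey, stock, season, cfg.min_temp_coverage)
        ind = indicator_table[
            (indicator_table["stock"] == name) & (indicator_table["season"] == season)
        ]
        if pred.empty or ind.empty:
            log.warning("%s %s: no aligned predictor/indicator years", name, season)
            continue
        results = importance_pipeline(ind, pred, criterion=cfg.criterion)
        by_key[f"{name}|{season}"] = results
        for indicator, res in results.items():
            for f in res.fits:
                model_rows.append(
                    {
                        "stock": name,
                        "season": season,
                        "indicator": indicator,
                        "model": f.spec.label,
                        "k": f.k,
                        "n": f.n,
                        "loglik": f.loglik,
                        "ic": f.ic,
                        "delta": f.delta,
                        "weight": f.weight,
                        "rho": f.rho,
                    }
                )
            for p in PREDICTORS:
                importance_rows.append(
                    {
                        "stock": name,
                        "season": season,
                        "indicator": indicator,
                        "predictor": p,
                        "summed_weight": res.summed_weight[p],
                        "rank": res.rank[p],
                        "avg_coef_conditional": res.averaged_coefficient[p],
                        "avg_coef_full": res.full_average[p],
                        "tied": res.ties,
                    }
                )
    summaries = []
    for season in sorted({k.split("|")[1] for k in by_key}):
        season_results = {k.split("|")[0]: v for k, v in by_key.items() if k.endswith(f"|{season}")}
        summ = first_rank_proportions(season_results)
        summ.insert(0, "season", season)
        summaries.append(summ)
    summary = pd.concat(summaries, ignore_index=True) if summaries else pd.DataFrame()
    return pd.DataFrame(model_rows), pd.DataFrame(importance_rows), summary


def run_simulate(config: ScenarioConfig, seed: int, out_dir: str | Path) -> dict[str, Path]:
    """Write a synthetic survey/catch/strata/truth dataset to ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    survey, truth = simulate_survey(config, seed)
    catch = simulate_catch(config, seed, survey, truth)
    stock = make_stock(config, catch)
    paths = {
        "survey": out / "survey.csv",
        "catch": out / "catch.csv",
        "strata": out / "strata.json",
        "truth": out / "truth.json",
    }
    survey.to_csv(paths["survey"], index=False)
    pd.DataFrame(
        {"stock": config.stock_name, "year": catch.index, "catch": catch.values}
    ).to_csv(paths["catch"], index=False)
    write_strata_json(paths["strata"], {config.stock_name: stock})
    truth_json = {
        "cg_trend_km_per_yr": list(config.cg_trend),
        "inertia_nominal_km2": config.inertia_target,
        "beta_relF_x": config.beta_relF_x,
        "cg_path": truth.cg_path.to_dict(orient="list"),
        "log_relF": {int(k): float(v) for k, v in truth.log_relF.items()},
        "expected_positive_area": {int(k): float(v) for k, v in truth.expected_pa.items()},
        "seed": seed,
    }
    paths["truth"].write_text(json.dumps(truth_json, indent=1))
    log.info("synthetic dataset written to %s (seed %d)", out, seed)
    return paths
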