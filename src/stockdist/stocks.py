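"""Stock definitions and the canonical survey-table schema.

A survey table is a pandas DataFrame with one row per trawl station:

    year          int, 4-digit
    season        str, uppercase token (SPRING/FALL)
    stratum       str, stratum identifier
    lon, lat      decimal degrees
    depth_m       float, station depth (m)
    bottom_temp_c float, bottom temperature (degC), NaN when not recorded
    <stock>       float, biomass (kg per tow) for each stock column

A stock is defined by its per-season strata sets (lon/lat polygons with
declared areas in km^2) and an annual catch series (landings + discards).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from shapely.geometry import Polygon

from .geo import ReferenceFrame, build_frame, polygon_to_xy
from .influence import StratumPolygon

SURVEY_COLUMNS = ["year", "season", "stratum", "lon", "lat", "depth_m", "bottom_temp_c"]

#: First and last year of the NEFSC bottom trawl survey by season.
SURVEY_SPANS = {"SPRING": (1968, 2016), "FALL": (1963, 2016)}


def survey_series_length(season: str, last_year: int | None = None) -> int:
    """Number of annual surveys for a season through ``last_year``.

    The spring series starts in 1968 and the fall series in 1963; through
    2016 that is 49 spring and 54 fall surveys.
    """
    first, default_last = SURVEY_SPANS[season.upper()]
    last = default_last if last_year is None else last_year
    return last - first + 1


@dataclass
class SeasonStrata:
    """The strata defining a stock's area for one season."""

    polygons: dict[str, Polygon]  # stratum id -> lon/lat polygon
    areas: dict[str, float]  # stratum id -> km^2

    @property
    def total_area(self) -> float:
        return float(sum(self.areas.values()))

    def frame(self, km_per_degree: float | None = None, midpoint: str = "bbox") -> ReferenceFrame:
        kwargs = {} if km_per_degree is None else {"km_per_degree": km_per_degree}
        return build_frame(self.polygons.values(), midpoint=midpoint, **kwargs)

    def km_strata(self, frame: ReferenceFrame) -> list[StratumPolygon]:
        """Strata re-expressed in the km frame, with their declared areas."""
        return [
            StratumPolygon(sid, polygon_to_xy(poly, frame), self.areas[sid])
            for sid, poly in self.polygons.items()
        ]


@dataclass
class StockDefinition:
    """Stock name, per-season strata, and the annual catch series."""

    name: str
    strata: dict[str, SeasonStrata]  # season token -> strata
    catch: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))  # year -> catch

    def season_strata(self, season: str) -> SeasonStrata:
        try:
            return self.strata[season]
        except KeyError:
            raise KeyError(f"stock {self.name!r} has no strata defined for season {season!r}")


def select_survey(survey: pd.DataFrame, stock: StockDefinition, season: str) -> pd.DataFrame:
    """Rows of ``survey`` in the stock's strata for one season."""
    strata = stock.season_strata(season)
    mask = (survey["season"] == season) & survey["stratum"].isin(strata.polygons)
    return survey.loc[mask]
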