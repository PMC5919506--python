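"""Shared fixtures: hand-sized station sets and a small 3-stratum survey."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import Polygon, box

from stockdist.geo import KM_PER_DEGREE, ReferenceFrame
from stockdist.stocks import SeasonStrata, StockDefinition


@pytest.fixture
def three_station():
    """The worked three-station example: w=(1,2,1), z=(4,1,2)."""
    return {
        "x": np.array([0.0, 10.0, 0.0]),
        "y": np.array([0.0, 0.0, 10.0]),
        "w": np.array([1.0, 2.0, 1.0]),
        "z": np.array([4.0, 1.0, 2.0]),
        "depth": np.array([10.0, 20.0, 40.0]),
    }


def _km_rect(frame: ReferenceFrame, x0, y0, x1, y1) -> Polygon:
    """Lon/lat polygon whose km-frame image is the rectangle (x0,y0,x1,y1)."""
    from stockdist.geo import polygon_from_xy

    return polygon_from_xy(box(x0, y0, x1, y1), frame)


@pytest.fixture
def small_stock():
    """A cod-shaped small stock: 3 strata (40x40 km each) in one season."""
    origin_lon, origin_lat = -70.0, 42.0
    lat_max = origin_lat + 40.0 / KM_PER_DEGREE
    frame = ReferenceFrame(origin_lon, origin_lat, 0.5 * (origin_lat + lat_max))
    polys = {
        "A": _km_rect(frame, 0, 0, 40, 40),
        "B": _km_rect(frame, 40, 0, 80, 40),
        "C": _km_rect(frame, 80, 0, 120, 40),
    }
    areas = {"A": 1600.0, "B": 1600.0, "C": 1600.0}
    strata = SeasonStrata(polygons=polys, areas=areas)
    return StockDefinition(name="COD", strata={"SPRING": strata})


@pytest.fixture
def small_survey(small_stock):
    """5 years of stations in the small stock's strata, seeded and complete."""
    rng = np.random.default_rng(42)
    frame = small_stock.strata["SPRING"].frame()
    rows = []
    for year in range(2000, 2005):
        for si, sid in enumerate(["A", "B", "C"]):
            for _ in range(4):
                x = rng.uniform(40 * si, 40 * (si + 1))
                y = rng.uniform(0, 40)
                lon = frame.origin_lon + x / (frame.km_per_degree * frame.cos_mid)
                lat = frame.origin_lat + y / frame.km_per_degree
                rows.append(
                    {
                        "year": year,
                        "season": "SPRING",
                        "stratum": sid,
                        "lon": lon,
                        "lat": lat,
                        "depth_m": 50.0 + y,
                        "bottom_temp_c": 6.0 + 0.01 * x,
                        "COD": rng.gamma(2.0, 2.0) if rng.uniform() > 0.2 else 0.0,
                    }
                )
    return pd.DataFrame(rows)


def raster_voronoi_weights(x, y, boundary, n_px=2000):
    """Brute-force oracle: nearest-station rasterization of the boundary."""
    from scipy.spatial import cKDTree
    import shapely

    minx, miny, maxx, maxy = boundary.bounds
    xs = np.linspace(minx, maxx, n_px, endpoint=False) + (maxx - minx) / n_px / 2
    ys = np.linspace(miny, maxy, n_px, endpoint=False) + (maxy - miny) / n_px / 2
    gx, gy = np.meshgrid(xs, ys)
    gx, gy = gx.ravel(), gy.ravel()
    inside = shapely.contains_xy(boundary, gx, gy)
    gx, gy = gx[inside], gy[inside]
    tree = cKDTree(np.column_stack([x, y]))
    _, idx = tree.query(np.column_stack([gx, gy]))
    px_area = ((maxx - minx) / n_px) * ((maxy - miny) / n_px)
    counts = np.bincount(idx, minlength=len(x))
    return counts * px_area
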