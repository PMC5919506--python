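"""Geographical referencing: longitude/latitude to a per-stock Euclidean km frame.

Distance-based indicators (center of gravity, inertia) require a Euclidean
coordinate system. Each stock gets a fixed reference frame with its origin at
the minimum longitude/latitude of the stock's survey strata; latitude converts
at a constant km-per-degree and longitude is scaled by the cosine of the
strata's midpoint latitude. One frame per stock x season is used for all
years so trends are comparable across years.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal

import numpy as np
from shapely.geometry import Polygon
from shapely.ops import transform as shapely_transform

#: km per degree of latitude on a sphere of mean radius 6371 km (pi*6371/180).
KM_PER_DEGREE = 111.195


@dataclass(frozen=True)
class ReferenceFrame:
    """Euclidean km frame anchored at the strata bounding-box minimum.

    Attributes
    ----------
    origin_lon, origin_lat
        Decimal degrees; the (0, 0) of the km frame.
    midpoint_lat
        Latitude whose cosine scales longitude degrees to km.
    km_per_degree
        km per degree of latitude (and of longitude at the equator).
    """

    origin_lon: float
    origin_lat: float
    midpoint_lat: float
    km_per_degree: float = KM_PER_DEGREE

    @property
    def cos_mid(self) -> float:
        return math.cos(math.radians(self.midpoint_lat))


def build_frame(
    strata_polygons: Iterable[Polygon],
    km_per_degree: float = KM_PER_DEGREE,
    midpoint: Literal["bbox", "centroid"] = "bbox",
) -> ReferenceFrame:
    """Build the reference frame for a stock from its strata polygons.

    The origin is the componentwise minimum over all polygon vertices. The
    midpoint latitude is the bounding-box latitude midpoint by default, or the
    area-weighted centroid latitude with ``midpoint="centroid"``.
    """
    polys = [p for p in strata_polygons]
    if not polys:
        raise ValueError("cannot build a reference frame from an empty strata set")
    minx = min(p.bounds[0] for p in polys)
    miny = min(p.bounds[1] for p in polys)
    maxy = max(p.bounds[3] for p in polys)
    if midpoint == "bbox":
        mid = 0.5 * (miny + maxy)
    elif midpoint == "centroid":
        areas = np.array([p.area for p in polys])
        lats = np.array([p.centroid.y for p in polys])
        mid = float(np.average(lats, weights=areas))
    else:  # pragma: no cover - guarded by Literal
        raise ValueError(f"unknown midpoint rule {midpoint!r}")
    return ReferenceFrame(minx, miny, mid, km_per_degree)


def to_xy(lon, lat, frame: ReferenceFrame):
    """Convert decimal degrees to km east/north of the frame origin.

    Accepts scalars or arrays; returns ``(x, y)`` of the same shape.
    """
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    x = (lon - frame.origin_lon) * frame.km_per_degree * frame.cos_mid
    y = (lat - frame.origin_lat) * frame.km_per_degree
    return x if x.ndim else float(x), y if y.ndim else float(y)


def from_xy(x, y, frame: ReferenceFrame):
    """Exact inverse of :func:`to_xy`; km back to decimal degrees."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    lon = frame.origin_lon + x / (frame.km_per_degree * frame.cos_mid)
    lat = frame.origin_lat + y / frame.km_per_degree
    return lon if lon.ndim else float(lon), lat if lat.ndim else float(lat)


def polygon_to_xy(poly: Polygon, frame: ReferenceFrame) -> Polygon:
    """Re-express a lon/lat polygon in the km frame (vertex-wise)."""
    return shapely_transform(lambda lon, lat: to_xy(lon, lat, frame), poly)


def polygon_from_xy(poly: Polygon, frame: ReferenceFrame) -> Polygon:
    """Re-express a km-frame polygon in lon/lat (vertex-wise)."""
    return shapely_transform(lambda x, y: from_xy(x, y, frame), poly)
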