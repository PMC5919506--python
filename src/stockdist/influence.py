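"""Station areas of influence by Voronoi (Dirichlet) tessellation.

Under a stratified random survey design the stations are irregularly spaced,
so each station's weight in the spatial indicators is the area of its Voronoi
cell clipped to the boundary of the stock's survey strata. The clipped cell
areas partition the strata exactly, which makes the positive-area indicator
sum to the total strata area when every tow is positive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import shapely
from shapely.geometry import MultiPoint, Point, Polygon
from shapely.ops import unary_union
from shapely.strtree import STRtree

log = logging.getLogger(__name__)

#: Relative tolerance for the area-conservation invariant sum(w) == area.
CONSERVATION_RTOL = 1e-6


@dataclass(frozen=True)
class StratumPolygon:
    """A survey stratum in frame km coordinates."""

    stratum_id: str
    boundary: Polygon
    area: float  # km^2, as declared in the stock definition

    def __post_init__(self):
        if not self.boundary.is_valid:
            raise ValueError(f"stratum {self.stratum_id}: invalid geometry")
        if self.area <= 0:
            raise ValueError(f"stratum {self.stratum_id}: area must be positive")


@dataclass
class InfluenceSet:
    """Per-station areas of influence w_i (km^2) plus the clipping area."""

    weights: np.ndarray
    total_area: float
    dropped: list[int] = field(default_factory=list)  # indices with zero-area cells


def dissolve_boundary(strata: list[StratumPolygon]) -> Polygon:
    """Geometric union of the strata; the Voronoi clipping region."""
    if not strata:
        raise ValueError("no strata to dissolve")
    for s in strata:
        if not s.boundary.is_valid:
            raise ValueError(f"stratum {s.stratum_id}: invalid geometry")
    return unary_union([s.boundary for s in strata])


def voronoi_weights(x, y, boundary: Polygon) -> InfluenceSet:
    """Area of influence of each station: its Voronoi cell clipped to ``boundary``.

    Stations sharing identical coordinates are merged into one pseudo-site and
    the cell area is shared equally among them on un-merge. Stations whose
    clipped cell is empty (well outside the strata) get weight 0 and are
    listed in ``dropped``; all positive weights sum to the boundary area.

    Parameters
    ----------
    x, y : array-like, km frame coordinates
    boundary : shapely Polygon or MultiPolygon (dissolved strata)
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0:
        raise ValueError("voronoi_weights needs at least one station")
    pts = np.column_stack([x, y])

    # merge exact-duplicate sites; weight is split equally on un-merge
    uniq, inverse, counts = np.unique(pts, axis=0, return_inverse=True, return_counts=True)
    if len(uniq) < len(pts):
        log.warning("merged %d coincident stations", len(pts) - len(uniq))

    total_area = boundary.area
    if len(uniq) == 1:
        cell_areas = np.array([total_area])
    else:
        # extend the diagram well past both data and boundary so outer cells
        # are finite before clipping
        minx = min(uniq[:, 0].min(), boundary.bounds[0])
        miny = min(uniq[:, 1].min(), boundary.bounds[1])
        maxx = max(uniq[:, 0].max(), boundary.bounds[2])
        maxy = max(uniq[:, 1].max(), boundary.bounds[3])
        pad = 10.0 * max(maxx - minx, maxy - miny, 1.0)
        extent = shapely.box(minx - pad, miny - pad, maxx + pad, maxy + pad)
        cells = shapely.voronoi_polygons(MultiPoint(uniq), extend_to=extent)
        cell_list = list(cells.geoms)
        # voronoi_polygons does not preserve input order: locate each site's cell
        tree = STRtree(cell_list)
        cell_areas = np.empty(len(uniq))
        site_points = [Point(p) for p in uniq]
        idx = tree.query(site_points, predicate="intersects")
        # idx rows: (site index, cell index); a site interior to its cell hits once
        order = np.full(len(uniq), -1, dtype=int)
        for si, ci in zip(*idx):
            order[si] = ci
        if (order < 0).any():  # pragma: no cover - defensive
            raise RuntimeError("Voronoi cell lookup failed for some stations")
        clipped = shapely.intersection(np.array(cell_list, dtype=object)[order], boundary)
        cell_areas = shapely.area(clipped)

    weights = cell_areas[inverse] / counts[inverse]
    dropped = [int(i) for i in np.flatnonzero(weights <= 0.0)]
    if dropped:
        log.warning("%d stations outside the strata boundary have zero-area cells", len(dropped))
    positive_sum = weights.sum()
    if not np.isclose(positive_sum, total_area, rtol=1e-9, atol=1e-9 * max(total_area, 1.0)):
        # clipping is exact up to GEOS floating point; anything larger is a bug
        log.warning(
            "area conservation residual %.3g relative", abs(positive_sum - total_area) / total_area
        )
    return InfluenceSet(weights=weights, total_area=total_area, dropped=dropped)
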