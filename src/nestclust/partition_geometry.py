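"""Thiessen (Voronoi) partitioning of the landscape by cluster membership.

Every location inside a site's Thiessen cell is closer to that site than to
any other site; dissolving cells by cluster membership therefore partitions
the whole study area into contiguous population-unit polygons.  One Voronoi
diagram is computed over all sites and reused across cluster levels, so a
coarser level's polygons are exact unions of the finer level's polygons.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import MultiPoint, Point, Polygon
from shapely.ops import unary_union, voronoi_diagram

from .errors import InvalidInputError

AREA_RTOL = 1e-6


@dataclass
class PartitionMap:
    level_index: int
    polygons: dict                 # cluster_id -> (Multi)Polygon
    boundary: Polygon
    multipart: list = field(default_factory=list)  # cluster ids with >1 part

    def neighbors(self, cluster_id) -> list:
        """Cluster ids whose polygons share a boundary with this one."""
        poly = self.polygons[cluster_id]
        out = []
        for other, p in sorted(self.polygons.items(), key=lambda kv: str(kv[0])):
            if other == cluster_id:
                continue
            inter = poly.intersection(p)
            if not inter.is_empty and inter.length > 0:
                out.append(other)
        return out


def default_boundary(sites: pd.DataFrame, margin: float | None = None) -> Polygon:
    """Convex hull of the sites buffered by a margin (default: 5% of the
    hull diagonal, at least one unit)."""
    pts = MultiPoint([(x, y) for x, y in zip(sites["x"], sites["y"])])
    hull = pts.convex_hull
    if margin is None:
        xmin, ymin, xmax, ymax = hull.bounds
        margin = max(0.05 * float(np.hypot(xmax - xmin, ymax - ymin)), 1.0)
    return hull.buffer(margin)


def thiessen_cells(sites: pd.DataFrame, boundary: Polygon) -> dict:
    """Voronoi cell per site, clipped to the boundary.

    Raises when sites fall outside the boundary or share coordinates.  A
    single site owns the whole boundary.
    """
    pts = [(sid, Point(x, y)) for sid, x, y in zip(sites["site_id"], sites["x"], sites["y"])]
    outside = [sid for sid, p in pts if not boundary.covers(p)]
    if outside:
        raise InvalidInputError(f"sites outside the study boundary: {outside[:10]}")
    coords = {}
    for sid, p in pts:
        key = (p.x, p.y)
        if key in coords:
            raise InvalidInputError(
                f"duplicate site coordinates at {key}: {coords[key]!r} and {sid!r}"
            )
        coords[key] = sid
    if len(pts) == 1:
        return {pts[0][0]: boundary}
    diagram = voronoi_diagram(
        MultiPoint([p for _, p in pts]), envelope=boundary.buffer(boundary.length)
    )
    cells = {}
    for raw in diagram.geoms:
        owners = [sid for sid, p in pts if raw.covers(p)]
        if len(owners) != 1:  # pragma: no cover - GEOS guarantees one generator
            raise InvalidInputError(f"Voronoi cell with {len(owners)} generating sites")
        cells[owners[0]] = raw.intersection(boundary)
    missing = [sid for sid, _ in pts if sid not in cells]
    if missing:  # pragma: no cover
        raise InvalidInputError(f"no Voronoi cell for sites: {missing[:10]}")
    return cells


def dissolve(cells: dict, assignment: pd.Series, level_index: int = 0,
             boundary: Polygon | None = None) -> PartitionMap:
    """Union member cells per cluster into population-unit polygons.

    Checks the tessellation invariants: interior-disjoint polygons whose
    areas sum to the boundary area (relative tolerance 1e-6).  Clusters
    whose polygons come out multi-part are reported in ``multipart`` —
    after adjacency enforcement only detached-site singletons should
    appear there.
    """
    unassigned = [s for s in cells if s not in assignment.index or pd.isna(assignment.get(s))]
    if unassigned:
        raise InvalidInputError(f"sites without cluster assignment: {unassigned[:10]}")
    if boundary is None:
        boundary = unary_union(list(cells.values()))
    groups: dict = {}
    for sid, cell in cells.items():
        groups.setdefault(assignment[sid], []).append(cell)
    polygons = {cid: unary_union(parts) for cid, parts in groups.items()}
    multipart = sorted(
        (cid for cid, poly in polygons.items() if poly.geom_type != "Polygon"),
        key=str,
    )
    total = sum(p.area for p in polygons.values())
    if abs(total - boundary.area) > AREA_RTOL * boundary.area:
        raise InvalidInputError(
            f"dissolved polygons cover {total}, boundary area is {boundary.area}"
        )
    return PartitionMap(
        level_index=level_index, polygons=polygons, boundary=boundary, multipart=multipart
    )


def partition_levels(
    sites: pd.DataFrame, levels, boundary: Polygon | None = None
) -> list[PartitionMap]:
    """PartitionMap per cluster level from a single shared Voronoi diagram."""
    if boundary is None:
        boundary = default_boundary(sites)
    cells = thiessen_cells(sites, boundary)
    return [
        dissolve(cells, lv.assignment, level_index=lv.level_index, boundary=boundary)
        for lv in levels
    ]
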