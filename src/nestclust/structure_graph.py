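"""Population-structure graphs from least-cost routing.

Sites of high fidelity (leks) are connected by least-cost paths over a
resistance surface; a minimum spanning tree over accumulated LCP costs gives
the fully connected population structure, which is then decomposed into
hierarchical tiers by removing edges that exceed dispersal-rule thresholds
(e.g., a 15 km inter-site distance).  Sites left without a retained edge in
a tier are *detached* and are carried as singleton units until a more
connected tier re-attaches them.

Routing runs on the 8-connected lattice of cell centers; the cost of a move
between neighboring cells is the mean of the two cell resistances times the
center-to-center distance (``cell_size`` orthogonally, ``cell_size·√2``
diagonally).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix, csr_matrix
from scipy.sparse.csgraph import dijkstra
from scipy.spatial import Delaunay, QhullError, cKDTree

from .errors import ConfigError, InvalidInputError, UnreachableSiteError
from .raster import Raster

# ResistanceSurface is structurally a Raster: strictly positive non-nodata
# cells, cell centers as traversal nodes.
ResistanceSurface = Raster

SQRT2 = float(np.sqrt(2.0))


@dataclass(frozen=True)
class StructureEdge:
    site_a: object
    site_b: object
    cost: float                 # accumulated cost-weighted distance
    euclid_length: float        # straight-line site distance, m
    path: tuple | None = None   # optional cell-center polyline ((x, y), ...)


@dataclass
class StructureTier:
    tier_index: int             # 1 = least connected
    edges: list                 # [(site_a, site_b), ...] retained
    subgraphs: list             # [frozenset of site ids, ...]
    detached: list              # site ids with no retained edge

    def membership(self) -> dict:
        """site id -> subgraph index (detached sites excluded)."""
        out = {}
        for i, sg in enumerate(self.subgraphs):
            for s in sg:
                out[s] = i
        return out


# ---------------------------------------------------------------------------
# lattice routing


def _lattice_graph(surface: Raster) -> csr_matrix:
    """Sparse symmetric cost graph over valid cell centers."""
    g = surface.grid
    nrows, ncols = g.shape
    valid = surface.mask()
    idx = np.arange(nrows * ncols).reshape(nrows, ncols)
    rows, cols, data = [], [], []
    # orthogonal + diagonal half-offsets; symmetry handled by directed=False
    for dr, dc, dist in ((0, 1, 1.0), (1, 0, 1.0), (1, 1, SQRT2), (1, -1, SQRT2)):
        r0 = slice(0, nrows - dr)
        r1 = slice(dr, nrows)
        if dc >= 0:
            c0, c1 = slice(0, ncols - dc), slice(dc, ncols)
        else:
            c0, c1 = slice(-dc, ncols), slice(0, ncols + dc)
        ok = valid[r0, c0] & valid[r1, c1]
        w = 0.5 * (g[r0, c0] + g[r1, c1]) * (dist * surface.cell_size)
        rows.append(idx[r0, c0][ok])
        cols.append(idx[r1, c1][ok])
        data.append(w[ok])
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    data = np.concatenate(data)
    n = nrows * ncols
    return coo_matrix((data, (rows, cols)), shape=(n, n)).tocsr()


def _site_node(surface: Raster, x: float, y: float, site) -> int:
    r, c = surface.cell_of(x, y)
    if surface.grid[r, c] == surface.nodata:
        raise UnreachableSiteError(site, site, reason="site falls on a nodata cell")
    return r * surface.ncols + c


def least_cost_path(
    surface: Raster,
    source: tuple[float, float],
    target: tuple[float, float],
    source_id=None,
    target_id=None,
) -> StructureEdge:
    """Minimal accumulated-cost route between two points on the surface.

    Sites are snapped to their containing cell centers; the returned path is
    the cell-center polyline.  Raises UnreachableSiteError if either site is
    on nodata or no route exists.
    """
    source_id = source_id if source_id is not None else tuple(source)
    target_id = target_id if target_id is not None else tuple(target)
    euclid = float(np.hypot(target[0] - source[0], target[1] - source[1]))
    s = _site_node(surface, *source, source_id)
    t = _site_node(surface, *target, target_id)
    if s == t:
        return StructureEdge(source_id, target_id, 0.0, euclid,
                             path=(surface.cell_center(*divmod(s, surface.ncols)),))
    graph = _lattice_graph(surface)
    dist, pred = dijkstra(graph, directed=False, indices=s, return_predecessors=True)
    if not np.isfinite(dist[t]):
        raise UnreachableSiteError(source_id, target_id)
    nodes = [t]
    while nodes[-1] != s:
        nodes.append(pred[nodes[-1]])
    nodes.reverse()
    path = tuple(surface.cell_center(*divmod(int(n), surface.ncols)) for n in nodes)
    return StructureEdge(source_id, target_id, float(dist[t]), euclid, path=path)


# ---------------------------------------------------------------------------
# candidate pairs and the LCP-MST


def _candidate_pairs(sites: pd.DataFrame, neighbor_rule: str, k: int) -> set[tuple]:
    ids = sites["site_id"].to_numpy()
    xy = sites[["x", "y"]].to_numpy(float)
    n = len(ids)
    pairs: set[tuple] = set()

    def add(i: int, j: int) -> None:
        a, b = ids[i], ids[j]
        if a == b:
            return
        pairs.add((a, b) if _key(a) < _key(b) else (b, a))

    if neighbor_rule == "delaunay" and n >= 4:
        try:
            tri = Delaunay(xy)
            for simplex in tri.simplices:
                for u in range(3):
                    add(simplex[u], simplex[(u + 1) % 3])
            return pairs
        except QhullError:
            pass  # degenerate geometry (collinear sites): fall through to knn
    if neighbor_rule in ("delaunay", "knn"):
        kk = min(max(k, 1), n - 1) if neighbor_rule == "knn" else n - 1
        if n <= kk + 1 or neighbor_rule == "delaunay":
            # small or degenerate: complete graph
            for i in range(n):
                for j in range(i + 1, n):
                    add(i, j)
            return pairs
        tree = cKDTree(xy)
        _, nbrs = tree.query(xy, k=kk + 1)
        for i in range(n):
            for j in nbrs[i][1:]:
                add(i, int(j))
        return pairs
    raise ConfigError(f"unknown neighbor_rule {neighbor_rule!r}")


def _key(site) -> tuple:
    return (str(type(site).__name__ != "str"), str(site))


def build_lcp_mst(
    sites: pd.DataFrame,
    surface: Raster,
    neighbor_rule: str = "delaunay",
    k: int = 8,
    keep_paths: bool = False,
) -> nx.Graph:
    """Minimum spanning forest over least-cost-path costs.

    Candidate edges come from the neighbor rule (Delaunay triangulation by
    default, or k-nearest neighbors); LCP costs are computed once per source
    site via Dijkstra on the lattice.  Unreachable sites are recorded in
    ``G.graph["detached"]`` rather than raising.  Ties in edge weight are
    broken by lexicographic site-id order (edges are inserted in sorted
    order and Kruskal's sort is stable).
    """
    if len(sites) < 2:
        raise InvalidInputError("at least 2 sites are required to build an MST")
    if sites["site_id"].duplicated().any():
        raise InvalidInputError("duplicate site_id in site table")

    pairs = sorted(_candidate_pairs(sites, neighbor_rule, k), key=lambda p: (_key(p[0]), _key(p[1])))
    loc = sites.set_index("site_id")
    graph = _lattice_graph(surface)
    node_of: dict = {}
    bad: set = set()
    for sid, row in loc.iterrows():
        try:
            node_of[sid] = _site_node(surface, row["x"], row["y"], sid)
        except UnreachableSiteError:
            bad.add(sid)

    by_source: dict = {}
    for a, b in pairs:
        if a in bad or b in bad:
            continue
        by_source.setdefault(a, []).append(b)

    cand = nx.Graph()
    for sid, row in loc.iterrows():
        cand.add_node(sid, x=float(row["x"]), y=float(row["y"]),
                      isolate=bool(row.get("isolate", False)))

    for a in sorted(by_source, key=_key):
        targets = by_source[a]
        src = node_of[a]
        tnodes = [node_of[b] for b in targets]
        if keep_paths:
            dist, pred = dijkstra(graph, directed=False, indices=src, return_predecessors=True)
        else:
            dist = dijkstra(graph, directed=False, indices=src)
            pred = None
        for b, tn in zip(targets, tnodes):
            d = dist[tn] if tn != src else 0.0
            if not np.isfinite(d):
                continue
            ra, rb = loc.loc[a], loc.loc[b]
            euclid = float(np.hypot(rb["x"] - ra["x"], rb["y"] - ra["y"]))
            path = None
            if pred is not None and tn != src:
                nodes = [tn]
                while nodes[-1] != src:
                    nodes.append(pred[nodes[-1]])
                nodes.reverse()
                path = tuple(
                    surface.cell_center(*divmod(int(n), surface.ncols)) for n in nodes
                )
            cand.add_edge(a, b, cost=float(d), euclid_length=euclid, path=path)

    mst = nx.minimum_spanning_tree(cand, weight="cost", algorithm="kruskal")
    mst.graph["detached"] = sorted(
        (s for s in cand.nodes if cand.degree(s) == 0), key=_key
    )
    return mst


# ---------------------------------------------------------------------------
# tier decomposition

TierRule = Callable[[dict, object, object], bool]  # (edge data, a, b) -> keep?


def distance_threshold_rule(max_euclid_m: float) -> TierRule:
    """Keep an edge only if its straight-line length is <= max_euclid_m."""

    def rule(data: dict, a, b) -> bool:
        return data["euclid_length"] <= max_euclid_m

    rule.threshold = max_euclid_m  # type: ignore[attr-defined]
    return rule


def _as_rule(spec) -> TierRule:
    if spec is None:
        return lambda data, a, b: True
    if callable(spec):
        return spec
    return distance_threshold_rule(float(spec))


def decompose_tiers(mst: nx.Graph, tier_rules: Sequence) -> list[StructureTier]:
    """Decompose the MST into nested population-structure tiers.

    ``tier_rules`` is ordered from most to least restrictive (tier 1 first);
    each entry is a Euclidean-length threshold in meters, ``None`` for a
    no-op, or a callable ``rule(edge_data, a, b) -> keep``.  Tier ``t``
    retains the edges passing rules ``t..T``, so edge sets are nested by
    construction.  Numeric thresholds must be non-decreasing.  Sites flagged
    with node attribute ``isolate`` keep no edges at any tier and appear as
    permanently separate singleton subgraphs (not detached).
    """
    if not tier_rules:
        raise ConfigError("tier_rules must contain at least one rule")
    thresholds = [r for r in tier_rules if isinstance(r, (int, float))]
    if any(b < a for a, b in zip(thresholds, thresholds[1:])):
        raise ConfigError(
            f"distance thresholds must be non-decreasing from tier 1 upward, got {thresholds}"
        )
    rules = [_as_rule(r) for r in tier_rules]

    isolates = {n for n, d in mst.nodes(data=True) if d.get("isolate")}
    tiers = []
    for t in range(1, len(rules) + 1):
        kept = []
        for a, b, data in mst.edges(data=True):
            if a in isolates or b in isolates:
                continue
            if all(rule(data, a, b) for rule in rules[t - 1 :]):
                e = (a, b) if _key(a) < _key(b) else (b, a)
                kept.append(e)
        sub = nx.Graph()
        sub.add_nodes_from(mst.nodes)
        sub.add_edges_from(kept)
        components = [frozenset(c) for c in nx.connected_components(sub)]
        subgraphs = sorted(
            (c for c in components if len(c) > 1 or next(iter(c)) in isolates),
            key=lambda c: min(_key(s) for s in c),
        )
        detached = sorted(
            (n for n in mst.nodes if sub.degree(n) == 0 and n not in isolates), key=_key
        )
        tiers.append(
            StructureTier(
                tier_index=t,
                edges=sorted(kept, key=lambda e: (_key(e[0]), _key(e[1]))),
                subgraphs=subgraphs,
                detached=detached,
            )
        )
    full = {frozenset(e) for e in tiers[-1].edges}
    expected = {
        frozenset((a, b))
        for a, b in mst.edges
        if a not in isolates and b not in isolates
    }
    if full != expected:
        raise ConfigError("the final tier rule must retain every MST edge")
    return tiers


def tier_graph(tier: StructureTier, mst: nx.Graph) -> nx.Graph:
    """Site-level graph of one tier, with MST edge attributes attached."""
    g = nx.Graph()
    g.add_nodes_from(mst.nodes(data=True))
    for a, b in tier.edges:
        g.add_edge(a, b, **mst.edges[a, b])
    return g
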