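"""Routing, MST and tier tests against independent small-scale oracles."""

import heapq
import itertools

import networkx as nx
import numpy as np
import pytest

import nestclust as nc
from nestclust.errors import ConfigError, InvalidInputError, UnreachableSiteError

from conftest import site_table, uniform_surface

SQRT2 = np.sqrt(2.0)


def dijkstra_oracle(grid: np.ndarray, cell: float, src: tuple, dst: tuple) -> float:
    """Independent shortest-path on the 8-connected lattice (heapq)."""
    nrows, ncols = grid.shape
    dist = {src: 0.0}
    heap = [(0.0, src)]
    while heap:
        d, node = heapq.heappop(heap)
        if node == dst:
            return d
        if d > dist.get(node, np.inf):
            continue
        r, c = node
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == dc == 0:
                    continue
                nr, nc_ = r + dr, c + dc
                if not (0 <= nr < nrows and 0 <= nc_ < ncols):
                    continue
                step = cell * (SQRT2 if dr and dc else 1.0)
                w = 0.5 * (grid[r, c] + grid[nr, nc_]) * step
                nd = d + w
                if nd < dist.get((nr, nc_), np.inf):
                    dist[(nr, nc_)] = nd
                    heapq.heappush(heap, (nd, (nr, nc_)))
    return np.inf


class TestLeastCostPath:
    def test_uniform_row_cost_is_distance(self):
        surface = uniform_surface(10, cell=100.0)
        edge = nc.least_cost_path(surface, (50.0, 50.0), (550.0, 50.0))
        assert edge.cost == pytest.approx(5 * 100.0)
        assert edge.euclid_length == pytest.approx(500.0)

    def test_routes_through_the_gap_in_a_costly_wall(self):
        grid = np.ones((9, 9))
        grid[4, :] = 1000.0
        grid[4, 7] = 1.0  # the gap
        surface = nc.Raster(grid, (0.0, 0.0), 1.0)
        edge = nc.least_cost_path(surface, (1.5, 0.5), (1.5, 8.5))
        oracle = dijkstra_oracle(grid, 1.0, surface.cell_of(1.5, 0.5), surface.cell_of(1.5, 8.5))
        assert edge.cost == pytest.approx(oracle)
        cols = {surface.cell_of(x, y)[1] for x, y in edge.path}
        assert 7 in cols  # detours through the gap column

    def test_identity_route(self):
        surface = uniform_surface(5)
        edge = nc.least_cost_path(surface, (150.0, 150.0), (150.0, 150.0))
        assert edge.cost == 0.0
        assert len(edge.path) == 1

    def test_nodata_site_raises(self):
        grid = np.ones((5, 5))
        grid[0, 0] = -9999.0
        surface = nc.Raster(grid, (0.0, 0.0), 100.0)
        with pytest.raises(UnreachableSiteError):
            nc.least_cost_path(surface, (50.0, 450.0), (450.0, 50.0))

    def test_nodata_sea_raises_naming_both_sites(self):
        grid = np.ones((5, 5))
        grid[:, 2] = -9999.0
        surface = nc.Raster(grid, (0.0, 0.0), 100.0)
        with pytest.raises(UnreachableSiteError, match="left.*right|right.*left"):
            nc.least_cost_path(surface, (50.0, 250.0), (450.0, 250.0),
                               source_id="left", target_id="right")

    def test_random_grids_match_independent_dijkstra(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            grid = rng.uniform(0.5, 10.0, size=(15, 15))
            surface = nc.Raster(grid, (0.0, 0.0), 30.0)
            r0, c0, r1, c1 = rng.integers(0, 15, size=4)
            src = surface.cell_center(int(r0), int(c0))
            dst = surface.cell_center(int(r1), int(c1))
            edge = nc.least_cost_path(surface, src, dst)
            oracle = dijkstra_oracle(grid, 30.0, (int(r0), int(c0)), (int(r1), int(c1)))
            assert edge.cost == pytest.approx(oracle, rel=1e-10)


def spanning_tree_minimum(graph: nx.Graph) -> float:
    """Brute-force minimum spanning tree weight by edge-subset enumeration."""
    edges = list(graph.edges(data="cost"))
    n = graph.number_of_nodes()
    best = np.inf
    for subset in itertools.combinations(edges, n - 1):
        g = nx.Graph()
        g.add_nodes_from(graph.nodes)
        g.add_edges_from((a, b) for a, b, _ in subset)
        if nx.is_connected(g):
            best = min(best, sum(w for _, _, w in subset))
    return best


class TestLcpMst:
    def test_smallest_two_of_three_triangle(self):
        # uniform surface; equilateral-ish triangle -> MST keeps the 2 cheap edges
        surface = uniform_surface(30, cell=100.0)
        sites = site_table([(250, 250), (450, 250), (250, 2250)])
        mst = nc.build_lcp_mst(sites, surface)
        assert mst.number_of_edges() == 2
        costs = sorted(d["cost"] for _, _, d in mst.edges(data=True))
        # the long hypotenuse edge is excluded
        assert costs[-1] < 2100.0

    def test_total_cost_matches_brute_force_on_random_layouts(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            grid = rng.uniform(0.5, 5.0, size=(12, 12))
            surface = nc.Raster(grid, (0.0, 0.0), 50.0)
            n = int(rng.integers(4, 8))
            coords = []
            cells = set()
            while len(coords) < n:
                r, c = int(rng.integers(12)), int(rng.integers(12))
                if (r, c) not in cells:
                    cells.add((r, c))
                    coords.append(surface.cell_center(r, c))
            sites = site_table(coords)
            mst = nc.build_lcp_mst(sites, surface)
            # rebuild the same candidate graph from pairwise LCP costs
            from nestclust.structure_graph import _candidate_pairs

            cand = nx.Graph()
            cand.add_nodes_from(sites["site_id"])
            loc = sites.set_index("site_id")
            for a, b in _candidate_pairs(sites, "delaunay", 8):
                e = nc.least_cost_path(
                    surface, (loc.loc[a, "x"], loc.loc[a, "y"]),
                    (loc.loc[b, "x"], loc.loc[b, "y"]),
                )
                cand.add_edge(a, b, cost=e.cost)
            total = sum(d["cost"] for _, _, d in mst.edges(data=True))
            assert total == pytest.approx(spanning_tree_minimum(cand), rel=1e-10)

    def test_collinear_sites_form_a_chain(self):
        surface = uniform_surface(40, cell=100.0)
        coords = [(150.0 + 800 * i, 150.0) for i in range(5)]
        sites = site_table(coords)
        mst = nc.build_lcp_mst(sites, surface)
        assert sorted(map(tuple, map(sorted, mst.edges))) == [(0, 1), (1, 2), (2, 3), (3, 4)]

    def test_site_order_invariance(self, sites, landscape):
        resistance, _ = landscape
        mst1 = nc.build_lcp_mst(sites, resistance)
        shuffled = sites.sample(frac=1.0, random_state=5).reset_index(drop=True)
        mst2 = nc.build_lcp_mst(shuffled, resistance)
        assert {frozenset(e) for e in mst1.edges} == {frozenset(e) for e in mst2.edges}

    def test_fewer_than_two_sites_rejected(self):
        surface = uniform_surface(5)
        with pytest.raises(InvalidInputError):
            nc.build_lcp_mst(site_table([(250, 250)]), surface)

    def test_unreachable_site_recorded_as_detached(self):
        grid = np.ones((9, 9))
        grid[:, 5] = -9999.0
        grid[:, 6:] = -9999.0
        grid[4, 8] = 1.0  # lone island cell
        surface = nc.Raster(grid, (0.0, 0.0), 100.0)
        sites = site_table([(150, 150), (250, 350), (850, 450)])
        mst = nc.build_lcp_mst(sites, surface)
        assert mst.graph["detached"] == [2]


class TestTiers:
    def test_threshold_drops_long_edges(self):
        surface = uniform_surface(60, cell=500.0)
        # chain with a 5 km and a 20 km hop
        sites = site_table([(250, 250), (5250, 250), (25250, 250)])
        mst = nc.build_lcp_mst(sites, surface)
        tiers = nc.decompose_tiers(mst, [15_000.0, None])
        t1 = tiers[0]
        assert [set(s) for s in t1.subgraphs] == [{0, 1}]
        assert t1.detached == [2]
        assert len(tiers[1].edges) == 2 and tiers[1].detached == []

    def test_noop_rule_reproduces_the_mst(self, structure):
        mst, _ = structure
        tiers = nc.decompose_tiers(mst, [None])
        assert len(tiers) == 1
        assert {frozenset(e) for e in tiers[0].edges} == {frozenset(e) for e in mst.edges}
        assert tiers[0].detached == []

    def test_edge_sets_nest_across_tiers(self, structure):
        mst, tiers = structure
        for lo, hi in zip(tiers, tiers[1:]):
            assert {frozenset(e) for e in lo.edges} <= {frozenset(e) for e in hi.edges}
            assert len(lo.subgraphs) + len(lo.detached) >= len(hi.subgraphs) + len(hi.detached)

    def test_every_site_in_exactly_one_subgraph_or_detached(self, structure):
        mst, tiers = structure
        for tier in tiers:
            seen = list(tier.detached)
            for sg in tier.subgraphs:
                seen.extend(sg)
            assert sorted(seen) == sorted(mst.nodes)

    def test_decreasing_thresholds_rejected(self, structure):
        mst, _ = structure
        with pytest.raises(ConfigError):
            nc.decompose_tiers(mst, [20_000.0, 10_000.0, None])

    def test_final_rule_must_keep_everything(self, structure):
        mst, _ = structure
        with pytest.raises(ConfigError):
            nc.decompose_tiers(mst, [10_000.0, 15_000.0])

    def test_isolates_stay_separate_singletons(self):
        surface = uniform_surface(30, cell=100.0)
        sites = site_table([(250, 250), (650, 250), (1050, 250)], isolate=[False, False, True])
        mst = nc.build_lcp_mst(sites, surface)
        tiers = nc.decompose_tiers(mst, [None])
        assert frozenset({2}) in set(tiers[0].subgraphs)
        assert tiers[0].detached == []
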