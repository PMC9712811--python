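"""Model enumeration, AICc scoring, correction passes and the full hierarchy."""

import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest

import nestclust as nc
from nestclust.errors import ConfigError
from nestclust.hierarchy import _rank_key

from conftest import site_table


class TestEnumerateModels:
    def test_pair_count_with_two_metrics(self):
        catalog = [f"f{i}" for i in range(8)]
        models = nc.enumerate_models(catalog, ("euclidean", "mahalanobis"), max_combo=2)
        assert len(models) == 72  # (8 + 28) * 2

    def test_single_feature_single_metric(self):
        assert len(nc.enumerate_models(["f"], ("euclidean",), max_combo=1)) == 1

    def test_duplicate_catalog_rejected(self):
        with pytest.raises(ConfigError):
            nc.enumerate_models(["a", "a"], ("euclidean",), 1)

    def test_cap_exceeded_raises_with_instruction(self):
        with pytest.raises(ConfigError, match="cap"):
            nc.enumerate_models([f"f{i}" for i in range(30)], ("euclidean",),
                                max_combo=5, cap=1000)

    def test_deterministic_order(self):
        a = nc.enumerate_models(["b", "a"], ("euclidean",), 2)
        b = nc.enumerate_models(["a", "b"], ("euclidean",), 2)
        assert a == b


class TestAicc:
    def test_unit_value(self):
        score = nc.aicc_from_sse(sse=4.0, n=4, k=2)
        assert score.aicc == pytest.approx(16.0)  # 4·ln(1) + 4 + 12
        assert not score.infeasible

    def test_zero_sse_flagged(self):
        score = nc.aicc_from_sse(sse=0.0, n=10, k=2)
        assert score.infeasible and score.reason == "zero_sse"
        assert math.isnan(score.aicc)

    def test_dof_guard(self):
        score = nc.aicc_from_sse(sse=1.0, n=4, k=3)
        assert score.infeasible and score.reason == "insufficient_dof"

    def test_perfect_fit_ranks_before_any_finite_aicc(self):
        perfect = nc.aicc_from_sse(0.0, 10, 2)
        finite = nc.aicc_from_sse(1e-9, 10, 2)
        spec = nc.ModelSpec(("f",), "euclidean")
        assert _rank_key(spec, perfect) < _rank_key(spec, finite)


class TestEnforceNesting:
    def test_majority_pulls_stray_member(self):
        prev = pd.Series({"a": 0, "b": 0, "c": 0})
        cur = pd.Series({"a": "X", "b": "X", "c": "Y"})
        out, moved = nc.enforce_nesting(prev, cur)
        assert moved == 1
        assert out.to_dict() == {"a": "X", "b": "X", "c": "X"}

    def test_already_nested_is_fixed_point(self):
        prev = pd.Series({"a": 0, "b": 0, "c": 1})
        cur = pd.Series({"a": "X", "b": "X", "c": "Y"})
        out, moved = nc.enforce_nesting(prev, cur)
        assert moved == 0 and out.equals(cur)

    def test_even_split_goes_to_lower_cluster_id(self):
        prev = pd.Series({"a": 0, "b": 0})
        cur = pd.Series({"a": 5, "b": 2})
        out, moved = nc.enforce_nesting(prev, cur)
        assert moved == 1
        assert set(out) == {2}


class TestEnforceAdjacency:
    def path_tier(self, labels):
        g = nx.path_graph(labels)
        return g

    def test_disconnected_member_moves_to_sharing_neighbor(self):
        tier = self.path_tier(["a", "b", "c", "d"])
        assignment = pd.Series({"a": 0, "b": 0, "c": 1, "d": 0})
        out, moved = nc.enforce_adjacency(assignment, tier)
        assert moved == 1
        assert out.to_dict() == {"a": 0, "b": 0, "c": 1, "d": 1}

    def test_connected_clusters_untouched(self):
        tier = self.path_tier(["a", "b", "c", "d"])
        assignment = pd.Series({"a": 0, "b": 0, "c": 1, "d": 1})
        out, moved = nc.enforce_adjacency(assignment, tier)
        assert moved == 0 and out.equals(assignment)

    def test_equal_components_keep_lower_min_site_side(self):
        # cluster 0 = {a, d} disconnected 1-1 around cluster 1 = {b, c};
        # the component holding the lower site id ('a') is "largest"
        tier = self.path_tier(["a", "b", "c", "d"])
        assignment = pd.Series({"a": 0, "b": 1, "c": 1, "d": 0})
        out, moved = nc.enforce_adjacency(assignment, tier)
        assert moved == 1
        assert out.to_dict() == {"a": 0, "b": 1, "c": 1, "d": 1}

    def test_detached_sites_exempt(self):
        tier = nx.Graph()
        tier.add_nodes_from(["a", "b", "z"])
        tier.add_edge("a", "b")
        assignment = pd.Series({"a": 0, "b": 0, "z": 0})
        out, moved = nc.enforce_adjacency(assignment, tier, detached={"z"})
        assert moved == 0


class TestRunHierarchy:
    def test_recovers_true_groups_at_the_matching_level(self, sites, multilevel):
        from sklearn.metrics import adjusted_rand_score

        by_site = multilevel[1].assignment.loc[sites["site_id"]]
        ari = adjusted_rand_score(sites["true_group"], by_site)
        assert ari == 1.0
        for rep in multilevel[0].reports.values():
            assert rep.adopted is not None or rep.note

    def test_generative_covariate_selected_on_connected_tier(self, sites, structure):
        # noise-free covariates over a single connected tier: the habitat
        # model separates the groups perfectly and must win model selection
        from sklearn.metrics import adjusted_rand_score

        from nestclust import fixtures

        sc = fixtures.SyntheticScenario(
            seed=11, n_groups=3, sites_per_group=8, group_separation=30_000.0,
            covariate_noise=0.0,
        )
        extent = (0.0, 0.0, 60_000.0, 60_000.0)
        resistance, rasters = fixtures.make_landscape(sc, extent, 1000.0)
        pure_sites = fixtures.make_sites(sc, extent)
        mst = nc.build_lcp_mst(pure_sites, resistance)
        tiers = nc.decompose_tiers(mst, [None])
        feats = nc.feature_table(rasters, pure_sites, radii=(0.0,), statistics=("mean",))
        configs = [nc.LevelConfig(1, 1, (8, 8), "select")]
        levels = nc.run_hierarchy(pure_sites, mst, tiers, feats, configs,
                                  stop_count=3, max_combo=1)
        assignment = levels[0].assignment.loc[pure_sites["site_id"]]
        assert adjusted_rand_score(pure_sites["true_group"], assignment) == 1.0
        (rep,) = levels[0].reports.values()
        assert any(f.startswith("habitat") for f in rep.adopted.features)
        assert rep.top[0][1].perfect  # zero SSE on the separating covariate

    def test_inherit_levels_reuse_the_selected_model(self, multilevel):
        select, inherit = multilevel[0], multilevel[1]
        assert inherit.mode == "inherit"
        inherited_specs = {
            rep.top[0][0] for rep in inherit.reports.values() if rep.top
        }
        selected_specs = {
            rep.adopted for rep in select.reports.values() if rep.adopted
        }
        assert inherited_specs <= selected_specs

    def test_nesting_invariant_across_levels(self, multilevel):
        for fine, coarse in zip(multilevel, multilevel[1:]):
            for cid, members in fine.clusters().items():
                parents = {coarse.assignment[s] for s in members}
                assert len(parents) == 1

    def test_cluster_count_non_increasing(self, multilevel):
        counts = [lv.n_clusters for lv in multilevel]
        assert counts == sorted(counts, reverse=True)

    def test_clusters_induce_connected_tier_subgraphs(self, multilevel, structure):
        mst, tiers = structure
        for lv in multilevel:
            tg = nc.tier_graph(tiers[lv.tier_index - 1], mst)
            detached = set(tiers[lv.tier_index - 1].detached)
            for cid, members in lv.clusters().items():
                members = members - detached
                if len(members) > 1:
                    assert nx.is_connected(tg.subgraph(members))

    def test_immediate_stop_when_target_already_met(
        self, sites, structure, features, level_configs
    ):
        mst, tiers = structure
        levels = nc.run_hierarchy(
            sites, mst, tiers, features, level_configs, stop_count=1000, max_combo=1
        )
        assert len(levels) == 1

    def test_determinism(self, sites, structure, features, level_configs):
        mst, tiers = structure
        a = nc.run_hierarchy(sites, mst, tiers, features, level_configs,
                             stop_count=1, max_combo=1)
        b = nc.run_hierarchy(sites, mst, tiers, features, level_configs,
                             stop_count=1, max_combo=1)
        for la, lb in zip(a, b):
            assert la.assignment.equals(lb.assignment)

    def test_singleton_subgraph_passed_through(self, landscape):
        resistance, rasters = landscape
        sc_sites = site_table([(5_000.0, 5_000.0), (5_500.0, 5_000.0), (40_000.0, 40_000.0)])
        mst = nc.build_lcp_mst(sc_sites, resistance)
        tiers = nc.decompose_tiers(mst, [15_000.0, None])
        feats = nc.feature_table(rasters, sc_sites, radii=(0.0,), statistics=("mean",))
        configs = [nc.LevelConfig(1, 1, (1, 2), "select")]
        levels = nc.run_hierarchy(sc_sites, mst, tiers, feats, configs, stop_count=1)
        # the far site is detached at tier 1 -> singleton cluster
        lv = levels[0]
        assert lv.assignment[2] not in {lv.assignment[0], lv.assignment[1]}


class TestRelativeImportance:
    def test_direct_ratio_matches_adopted_model_coverage(self, multilevel, sites):
        table = nc.relative_importance(multilevel, sites)
        select = multilevel[0]
        expected: dict = {}
        for rep in select.reports.values():
            if rep.adopted is None:
                continue
            for feat in rep.adopted.features:
                covname = feat.split("__")[0]
                expected[covname] = expected.get(covname, 0) + len(rep.member_sites)
        covs = table[(table["dimension"] == "covariate") & (table["tier"] == 1)]
        for covname, n in expected.items():
            got = covs[covs["value"] == covname]["importance"].iloc[0]
            assert got == pytest.approx(n / len(sites))

    def test_absent_feature_scores_zero(self, multilevel, sites):
        table = nc.relative_importance(multilevel, sites)
        vals = set(table[table["dimension"] == "covariate"]["value"])
        assert "nonexistent" not in vals

    def test_importances_bounded(self, multilevel, sites):
        table = nc.relative_importance(multilevel, sites)
        assert ((table["importance"] >= 0) & (table["importance"] <= 1.0 + 1e-12)).all()
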