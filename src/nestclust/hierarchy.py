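"""Agglomerative multi-level clustering with per-subgraph model selection.

Each cluster level groups the previous level's clusters (sites at level 1)
on the population-structure tier that governs the level.  Odd levels
*select*: for every subgraph of the tier, all candidate covariate
combinations × attribute metrics are clustered and ranked by AICc computed
from the within-cluster sum of squared errors, the top three models are
reported, and the best is adopted.  Even levels *inherit* the previous odd
level's winning model per subgraph and re-cluster under their own size
window, giving a gradual progression before new covariates and larger
landscapes are considered.

After each level, groupings are corrected to remain nested inside the
previous level (majority rule per previous cluster) and to be adjacent
(every cluster must induce a connected subgraph of the tier); both
correction counts are reported.  The hierarchy stops once a level reaches
the user's target number of populations.

AICc here is ``n·ln(SSE/n) + 2k + 2k(k+1)/(n−k−1)`` with ``k = #features +
1`` (one parameter per attribute dimension plus the variance term).  A
model whose SSE is exactly zero has no finite AICc (log of zero); scores
are flagged accordingly.  Constant attribute columns are excluded from
model enumeration before scoring — a constant covariate trivially yields
zero within-group sums of squares.  A zero-SSE score on a *non-constant*
feature set, by contrast, is a perfect separation of the units and is
ranked above every finite-AICc model (AICc → −∞ as SSE → 0).
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .covariates import group_median, standardize
from .errors import ConfigError, InvalidInputError, NestclustError
from .skater_engine import AttributeMetric, TreePartition, skater_partition
from .structure_graph import StructureTier, _key, tier_graph

MODEL_CAP = 100_000


@dataclass(frozen=True)
class ModelSpec:
    features: tuple[str, ...]      # feature-table column names, distinct
    metric_kind: str               # "euclidean" | "mahalanobis"

    def __post_init__(self) -> None:
        if len(set(self.features)) != len(self.features):
            raise ConfigError(f"duplicate features in model: {self.features}")


@dataclass
class ModelScore:
    sse: float
    n: int
    k: int
    aicc: float                    # NaN when infeasible
    infeasible: bool
    reason: str | None = None      # "zero_sse" | "insufficient_dof"

    @property
    def perfect(self) -> bool:
        return self.infeasible and self.reason == "zero_sse"


def aicc_from_sse(sse: float, n: int, k: int) -> ModelScore:
    """Small-sample AIC from a sum of squared errors; guards the log of zero."""
    if n - k - 1 < 1:
        return ModelScore(sse, n, k, math.nan, True, "insufficient_dof")
    if sse <= 0:
        return ModelScore(sse, n, k, math.nan, True, "zero_sse")
    value = n * math.log(sse / n) + 2 * k + (2 * k * (k + 1)) / (n - k - 1)
    return ModelScore(sse, n, k, value, False)


def score_model(partition: TreePartition, model: ModelSpec) -> ModelScore:
    """Score a fitted partition: SSE is its total within-cluster SSD."""
    n = sum(len(c) for c in partition.clusters)
    k = len(model.features) + 1
    return aicc_from_sse(partition.ssd_total, n, k)


def enumerate_models(
    catalog: list[str], metrics=("euclidean", "mahalanobis"), max_combo: int = 2,
    cap: int = MODEL_CAP,
) -> list[ModelSpec]:
    """All feature subsets of size 1..max_combo crossed with each metric."""
    if not catalog:
        raise ConfigError("empty feature catalog")
    if len(set(catalog)) != len(catalog):
        raise ConfigError("duplicate features in catalog")
    if max_combo < 1:
        raise ConfigError("max_combo must be >= 1")
    feats = sorted(catalog)
    total = sum(math.comb(len(feats), s) for s in range(1, min(max_combo, len(feats)) + 1))
    total *= len(metrics)
    if total > cap:
        raise ConfigError(
            f"{total} candidate models exceed the cap of {cap}; "
            "raise the cap or lower max_combo"
        )
    out = []
    for size in range(1, min(max_combo, len(feats)) + 1):
        for combo in itertools.combinations(feats, size):
            for metric in metrics:
                out.append(ModelSpec(features=combo, metric_kind=metric))
    return out


def _rank_key(spec: ModelSpec, score: ModelScore) -> tuple:
    # perfect fits first (AICc -> -inf), then finite AICc ascending;
    # ties toward fewer features, then name order
    return (
        0 if score.perfect else 1,
        score.aicc if not score.infeasible else math.inf,
        len(spec.features),
        spec.features,
        spec.metric_kind,
    )


@dataclass
class LevelConfig:
    level_index: int
    tier_index: int
    size_range: tuple[int, int]
    mode: str                      # "select" (odd) | "inherit" (even)

    def __post_init__(self) -> None:
        if self.mode not in ("select", "inherit"):
            raise ConfigError(f"mode must be 'select' or 'inherit', got {self.mode!r}")


def default_level_configs(n_tiers: int, min_leks_mid: int = 15) -> list[LevelConfig]:
    """Tier t governs levels 2t−1 (select) and 2t (inherit); geometric size
    windows starting at [2, 9], minimum capped at ``min_leks_mid`` units."""
    configs = []
    for level in range(1, 2 * n_tiers + 1):
        tier = (level + 1) // 2
        lo = min(min_leks_mid, int(math.ceil(2 * 2.2 ** (level - 1))))
        hi = 9 * 2 ** (level - 1)
        configs.append(
            LevelConfig(
                level_index=level,
                tier_index=tier,
                size_range=(lo, hi),
                mode="select" if level % 2 == 1 else "inherit",
            )
        )
    return configs


@dataclass
class SubgraphReport:
    subgraph_id: int
    units: list                                  # unit ids in the subgraph
    member_sites: frozenset
    top: list                                    # [(ModelSpec, ModelScore)] best-first, <= 3
    adopted: ModelSpec | None
    note: str | None = None


@dataclass
class ClusterLevel:
    level_index: int
    tier_index: int
    mode: str
    assignment: pd.Series                        # site_id -> cluster id (ints)
    reports: dict = field(default_factory=dict)  # subgraph_id -> SubgraphReport
    counts: dict = field(default_factory=dict)

    @property
    def n_clusters(self) -> int:
        return int(self.assignment.nunique())

    def clusters(self) -> dict:
        out: dict = {}
        for site, cid in self.assignment.items():
            out.setdefault(int(cid), set()).add(site)
        return out


# ---------------------------------------------------------------------------
# correction passes


def enforce_nesting(prev: pd.Series, current: pd.Series) -> tuple[pd.Series, int]:
    """Move each previous-level cluster wholly into the current cluster
    holding the majority of its sites (ties toward the lower cluster id)."""
    current = current.copy()
    moved = 0
    prev_groups: dict = {}
    for site, pc in prev.items():
        prev_groups.setdefault(pc, []).append(site)
    for pc in sorted(prev_groups, key=_key):
        members = prev_groups[pc]
        counts: dict = {}
        for s in members:
            counts[current[s]] = counts.get(current[s], 0) + 1
        target = min(counts, key=lambda c: (-counts[c], c))
        for s in members:
            if current[s] != target:
                current[s] = target
                moved += 1
    return current, moved


def enforce_adjacency(
    assignment: pd.Series,
    tier_g: nx.Graph,
    detached: set | frozenset = frozenset(),
    max_iterations: int = 100,
) -> tuple[pd.Series, int]:
    """Reassign sites until every cluster induces a connected tier subgraph.

    Members outside a cluster's largest component move to the neighboring
    cluster with which they share the most tier edges (ties toward the lower
    cluster id).  The largest component ties by the lower minimum site id.
    Detached sites are exempt.  Raises after ``max_iterations`` sweeps.
    """
    assignment = assignment.copy()
    total_moved = 0
    for _ in range(max_iterations):
        changed = 0
        for cid in sorted(assignment.unique()):
            members = {
                s for s, c in assignment.items() if c == cid and s not in detached
            }
            if not members:
                continue
            comps = sorted(
                nx.connected_components(tier_g.subgraph(members)),
                key=lambda c: (-len(c), min(_key(s) for s in c)),
            )
            if len(comps) <= 1:
                continue
            for comp in comps[1:]:
                for site in sorted(comp, key=_key):
                    shares: dict = {}
                    for nb in tier_g.neighbors(site):
                        nb_cid = assignment[nb]
                        if nb_cid != cid:
                            shares[nb_cid] = shares.get(nb_cid, 0) + 1
                    if not shares:
                        continue  # may resolve on a later sweep
                    target = min(shares, key=lambda c: (-shares[c], c))
                    assignment[site] = target
                    changed += 1
        if changed == 0:
            return assignment, total_moved
        total_moved += changed
    raise NestclustError(
        "adjacency enforcement did not converge within "
        f"{max_iterations} iterations; assignment state: {assignment.to_dict()}"
    )


# ---------------------------------------------------------------------------
# one level


def _contract(
    tier_g: nx.Graph, unit_of: pd.Series
) -> nx.Graph:
    """Tier graph contracted by unit membership; inter-unit edge weight is
    the minimum cost over the member-site edges joining the two units."""
    g = nx.Graph()
    for u in sorted(unit_of.unique(), key=_key):
        g.add_node(u)
    for a, b, data in tier_g.edges(data=True):
        ua, ub = unit_of[a], unit_of[b]
        if ua == ub:
            continue
        cost = data.get("cost", data.get("euclid_length", 1.0))
        if g.has_edge(ua, ub):
            if cost < g.edges[ua, ub]["cost"]:
                g.edges[ua, ub]["cost"] = cost
        else:
            g.add_edge(ua, ub, cost=cost)
    return g


def _spanning_tree(g: nx.Graph) -> nx.Graph:
    return nx.minimum_spanning_tree(g, weight="cost", algorithm="kruskal")


def run_level(
    prev_assignment: pd.Series,
    config: LevelConfig,
    tiers: list[StructureTier],
    mst: nx.Graph,
    site_features: pd.DataFrame,
    max_combo: int = 2,
    metrics=("euclidean", "mahalanobis"),
    prev_select: ClusterLevel | None = None,
    model_cap: int = MODEL_CAP,
) -> ClusterLevel:
    """Cluster the previous level's units on the level's tier.

    ``prev_assignment`` maps every site to its unit (site -> itself at
    level 1).  Returns the level before nesting/adjacency correction; see
    :func:`run_hierarchy` for the corrected pipeline.
    """
    tier = tiers[config.tier_index - 1]
    tg = tier_graph(tier, mst)
    contracted = _contract(tg, prev_assignment)

    members_of: dict = {}
    for site, u in prev_assignment.items():
        members_of.setdefault(u, set()).add(site)

    components = sorted(
        nx.connected_components(contracted),
        key=lambda c: min(_key(u) for u in c),
    )
    reports: dict = {}
    cluster_sets: list[set] = []  # sets of SITES
    for sg_id, comp in enumerate(components):
        units = sorted(comp, key=_key)
        member_sites = frozenset().union(*(members_of[u] for u in units))
        if len(units) < 2:
            cluster_sets.append(set(member_sites))
            reports[sg_id] = SubgraphReport(
                sg_id, units, member_sites, top=[], adopted=None,
                note="fewer than 2 units; passed through unclustered",
            )
            continue

        medians = pd.DataFrame(
            {
                col: group_median(prev_assignment, site_features[col])
                for col in site_features.columns
            }
        ).loc[units]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            z = standardize(medians)
        constant = set(z.attrs["constant_columns"])
        usable = [c for c in site_features.columns if c not in constant]
        sub_tree = _spanning_tree(contracted.subgraph(comp))

        if config.mode == "select":
            if not usable:
                cluster_sets.append(set(member_sites))
                reports[sg_id] = SubgraphReport(
                    sg_id, units, member_sites, top=[], adopted=None,
                    note="all attributes constant; passed through unclustered",
                )
                continue
            specs = enumerate_models(usable, metrics, max_combo, cap=model_cap)
        else:
            if prev_select is None:
                raise ConfigError(
                    f"level {config.level_index} inherits but no previous select level exists"
                )
            inherited = _matching_model(prev_select, member_sites)
            if inherited is None or all(f in constant for f in inherited.features):
                cluster_sets.append(set(member_sites))
                reports[sg_id] = SubgraphReport(
                    sg_id, units, member_sites, top=[], adopted=None,
                    note="no usable inherited model; passed through unclustered",
                )
                continue
            feats = tuple(f for f in inherited.features if f not in constant)
            specs = [ModelSpec(feats, inherited.metric_kind)]

        scored = []
        for spec in specs:
            X = z[list(spec.features)]
            metric = (
                AttributeMetric.euclidean()
                if spec.metric_kind == "euclidean"
                else AttributeMetric.mahalanobis(X.to_numpy())
            )
            partition = skater_partition(sub_tree, X, metric, config.size_range)
            score = score_model(partition, spec)
            if score.infeasible and not score.perfect:
                continue
            scored.append((spec, score, partition))
        if not scored:
            cluster_sets.append(set(member_sites))
            reports[sg_id] = SubgraphReport(
                sg_id, units, member_sites, top=[], adopted=None,
                note="no feasible model; passed through unclustered",
            )
            continue
        scored.sort(key=lambda t: _rank_key(t[0], t[1]))
        best_spec, best_score, best_partition = scored[0]
        for unit_cluster in best_partition.clusters:
            cluster_sets.append(set().union(*(members_of[u] for u in unit_cluster)))
        reports[sg_id] = SubgraphReport(
            sg_id, units, member_sites,
            top=[(s, sc) for s, sc, _ in scored[:3]],
            adopted=best_spec,
        )

    # deterministic cluster ids: order by smallest member site
    cluster_sets.sort(key=lambda c: min(_key(s) for s in c))
    assign = {}
    for cid, sset in enumerate(cluster_sets):
        for s in sset:
            assign[s] = cid
    assignment = pd.Series(assign).reindex(prev_assignment.index)
    if assignment.isna().any():
        raise InvalidInputError("some sites were not assigned to any cluster")
    assignment = assignment.astype(int)
    return ClusterLevel(
        level_index=config.level_index,
        tier_index=config.tier_index,
        mode=config.mode,
        assignment=assignment,
        reports=reports,
        counts={"n_detached": len(tier.detached)},
    )


def _matching_model(prev_select: ClusterLevel, member_sites: frozenset) -> ModelSpec | None:
    """Adopted model of the previous select-level subgraph holding the
    majority of this subgraph's sites."""
    best, best_overlap = None, -1
    for sg_id in sorted(prev_select.reports):
        rep = prev_select.reports[sg_id]
        overlap = len(rep.member_sites & member_sites)
        if overlap > best_overlap and rep.adopted is not None:
            best, best_overlap = rep.adopted, overlap
    return best


def _relabel(assignment: pd.Series) -> pd.Series:
    """Cluster ids 0..C−1 ordered by smallest member site id."""
    groups: dict = {}
    for site, cid in assignment.items():
        groups.setdefault(cid, []).append(site)
    order = sorted(groups, key=lambda c: min(_key(s) for s in groups[c]))
    remap = {old: new for new, old in enumerate(order)}
    return assignment.map(remap)


def run_hierarchy(
    sites: pd.DataFrame,
    mst: nx.Graph,
    tiers: list[StructureTier],
    site_features: pd.DataFrame,
    level_configs: list[LevelConfig],
    stop_count: int,
    max_combo: int = 2,
    metrics=("euclidean", "mahalanobis"),
    model_cap: int = MODEL_CAP,
) -> list[ClusterLevel]:
    """Run the full agglomerative hierarchy with correction passes.

    Levels are produced in config order; each raw level is corrected for
    nesting against the previous level, then for adjacency on its tier,
    then re-checked for nesting once.  The loop stops after the first level
    with at most ``stop_count`` clusters or when configs run out.
    """
    if stop_count < 1:
        raise ConfigError("stop_count must be >= 1")
    if not level_configs:
        raise ConfigError("no level configs")
    site_ids = pd.Index(sites["site_id"])
    prev_assignment = pd.Series(site_ids, index=site_ids)  # site -> itself
    levels: list[ClusterLevel] = []
    prev_select: ClusterLevel | None = None
    prev_level: ClusterLevel | None = None
    for config in level_configs:
        level = run_level(
            prev_assignment, config, tiers, mst, site_features,
            max_combo=max_combo, metrics=metrics, prev_select=prev_select,
            model_cap=model_cap,
        )
        tier = tiers[config.tier_index - 1]
        tg = tier_graph(tier, mst)
        detached = set(tier.detached)
        nest_moves = 0
        if prev_level is not None:
            level.assignment, nest_moves = enforce_nesting(
                prev_level.assignment, level.assignment
            )
        level.assignment, adj_moves = enforce_adjacency(
            level.assignment, tg, detached=detached
        )
        nest_moves_2 = 0
        if prev_level is not None:
            level.assignment, nest_moves_2 = enforce_nesting(
                prev_level.assignment, level.assignment
            )
        level.assignment = _relabel(level.assignment)
        level.counts.update(
            {
                "n_clusters": level.n_clusters,
                "nesting_reassignments": nest_moves + nest_moves_2,
                "adjacency_reassignments": adj_moves,
            }
        )
        levels.append(level)
        if level.mode == "select":
            prev_select = level
        prev_level = level
        prev_assignment = level.assignment
        if level.n_clusters <= stop_count:
            break
    return levels


def relative_importance(levels: list[ClusterLevel], sites: pd.DataFrame) -> pd.DataFrame:
    """Share of sites whose subgraph's top model includes each covariate,
    radius, statistic, and metric — per tier and pooled.

    importance = (sites in subgraphs whose adopted model includes the item)
    / (total sites).
    """
    select_levels = [lv for lv in levels if lv.mode == "select"]
    if not select_levels:
        raise InvalidInputError("relative_importance requires at least one select level")
    total = len(sites)
    rows = []
    scopes: dict = {}
    for lv in select_levels:
        for rep in lv.reports.values():
            if rep.adopted is None:
                continue
            n = len(rep.member_sites)
            items = {("metric", rep.adopted.metric_kind)}
            for feat in rep.adopted.features:
                parts = feat.split("__")
                if len(parts) == 3 and parts[1].startswith("r"):
                    items.add(("covariate", parts[0]))
                    items.add(("radius", parts[1][1:]))
                    items.add(("statistic", parts[2]))
                else:
                    items.add(("covariate", feat))
                    items.add(("statistic", "none"))
            for dim, value in items:
                scopes.setdefault((lv.tier_index, dim, value), 0)
                scopes[(lv.tier_index, dim, value)] += n
                scopes.setdefault(("pooled", dim, value), 0)
                scopes[("pooled", dim, value)] += n
    n_pooled_levels = len({lv.tier_index for lv in select_levels})
    for (tier, dim, value), count in sorted(scopes.items(), key=str):
        denom = total * (n_pooled_levels if tier == "pooled" else 1)
        rows.append(
            {
                "tier": tier,
                "dimension": dim,
                "value": value,
                "n_sites": count,
                "importance": count / denom,
            }
        )
    return pd.DataFrame(rows)
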