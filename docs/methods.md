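# Methods

## Problem and model

`nestclust` delineates hierarchically nested population units for species
that show strong fidelity to discrete sites (breeding leks, dens, colonies).
The method combines three ingredients: a landscape-connectivity graph over
the sites, a constrained regionalization of that graph driven by habitat
similarity, and a tessellation that turns cluster memberships into
wall-to-wall polygons. Telemetry provides an independent check that the
resulting units approximate geographic closure.

### Least-cost routing and structure tiers

Movement cost is modeled on the 8-connected lattice of raster cell centers.
A move between adjacent cells costs the arithmetic mean of the two cell
resistances times the center-to-center distance (cell size orthogonally,
cell size·√2 diagonally); resistance is a dimensionless multiplier ≥ some
positive floor, so cost has units of weighted meters. Sites are snapped to
their containing cell centers for routing. Candidate site pairs come from a
Delaunay triangulation by default (sparse, planar, contains all
nearest-neighbor pairs) or k-nearest neighbors; degenerate geometries
(collinear sites, n < 4) fall back to the complete graph. The minimum
spanning forest over accumulated least-cost costs is the fully connected
population structure; Kruskal with lexicographically ordered edge insertion
makes ties deterministic.

Structure tiers are produced constructively: tier *t* retains the edges
passing rules *t..T*, so the edge sets nest by definition and the subgraph
count is non-increasing in tier index. Rules are Euclidean-length
thresholds (must be non-decreasing with tier index), `None` (no-op), or
arbitrary predicates; the canonical example is a 15 km dispersal threshold
for tier 1. Sites with no retained edge in a tier are *detached* and are
carried as singleton clusters until a more connected tier re-attaches them.
Sites flagged `isolate` keep no edges at any tier and remain permanently
separate singleton subgraphs (e.g., known genetically isolated
populations). The final rule must retain every MST edge, which is validated
at decomposition time.

### Covariates

Zonal statistics use cell-center disk membership: a cell contributes when
its center lies within the closed disk of the given radius around the site
point (radius 0 means the containing cell). Statistics are the arithmetic
mean and the coefficient of variation, with the sample (n−1) standard
deviation in both the CV and the z-scores — the sample convention matters
at the small unit counts typical of coarse levels. A zero mean with nonzero
spread makes the CV undefined and is flagged missing rather than infinite.
Default radii are {30, 100, 200, 400, 800, 1600, 3200, 6400} m; any ladder
can be configured (radii below half the cell size cannot contain a cell
center and are skipped with a warning). Per clustering unit, member-site
values aggregate by median (even counts take the mean of the two central
values) and are z-scored per subgraph. Columns that come out constant are
zeroed and flagged: a constant attribute trivially drives the within-group
sum of squares to zero and admits no information-criterion score, so model
enumeration excludes them up front.

The *null covariate* — one uniform random integer in [0, 1,000,000] per
site — replaces the habitat catalog when measuring how much habitat
information actually contributes: it keeps the clustering machinery running
(a constant would not) while carrying no signal.

### SKATER engine

The partition objective is the within-cluster sum of squared deviations
(SSD) in attribute space, Euclidean or Mahalanobis. The Mahalanobis
covariance is pooled over all units of the subgraph (not per cluster) and
ridge-regularized with ε = 1e-8·trace(S)/p on the diagonal, which keeps it
positive definite and the result deterministic. Each greedy step scans
every remaining tree edge exhaustively, computes the gain
f(e) = SSD(cluster) − SSD(side A) − SSD(side B), filters by the minimum
group size, and applies the best cut; ties break toward the more balanced
cut and then the lexicographically smallest edge. The exhaustive scan
replaces the original SKATER expansion-tree heuristic: it makes the greedy
choice exactly verifiable against brute force and is cheap at the subgraph
sizes this workflow produces.

The native stopping rule is the size window — cut while any cluster exceeds
the maximum group size — because the hierarchy drives cluster counts
through per-level size ranges rather than a target k. Two secondary modes
exist: continue while positive-gain feasible cuts remain, and a classical
fixed-cluster-count mode. If an oversize cluster admits no feasible cut it
is left oversize with a warning rather than violating the minimum size.

### Hierarchy, model selection, corrections

Level ℓ clusters the previous level's clusters (sites at level 1) on the
tier scheduled for it; the default schedule gives tier *t* to levels 2t−1
and 2t. The tier graph is contracted by prior membership, with the
inter-unit edge weight equal to the minimum cost among the member-site
edges — contraction preserves the strongest connection. Unit attributes are
the per-unit medians, z-scored per subgraph; clustering runs on the minimum
spanning tree of each contracted subgraph.

At *select* (odd) levels, every feature subset of size 1..max_combo crossed
with each metric is clustered and scored by AICc from the SSE:
AICc = n·ln(SSE/n) + 2k + 2k(k+1)/(n−k−1) with k = #features + 1 (one
parameter per attribute dimension plus a variance term; this definition is
isolated in one function for easy revision). Scores with n − k − 1 < 1 are
infeasible and excluded. A zero-SSE score is flagged as having no finite
AICc; when it arises from a *non-constant* feature set it is a perfect
separation of the units, and the ranking places it above every finite-AICc
model (AICc → −∞ as SSE → 0; ties resolve toward fewer features, then name
order). The genuinely degenerate zero-SSE case — a constant covariate — is
already rejected by the constant-column flag before scoring. The top three
models per subgraph are reported and the best adopted. *Inherit* (even)
levels reuse the previous select level's winning model per subgraph
(matched by site-membership overlap) and re-cluster under their own size
window, so clusters grow gradually before new covariates and coarser
landscapes are considered. Subgraphs with fewer than two units, or where no
model is feasible, pass through unclustered with a log note.

Corrections run in a fixed order after each level: nesting (each previous
cluster moves wholly to the current cluster holding its strict majority of
sites; ties toward the lower cluster id), then adjacency (members outside a
cluster's largest tier component move to the neighboring cluster sharing
the most tier edges; equal-size components tie toward the one with the
lower minimum site id; iterated to a fixed point, error after 100 sweeps),
then one nesting re-check. Both reassignment counts are reported per level.
The hierarchy stops after the first level with at most `stop_count`
clusters.

Relative importance of a covariate, radius, statistic, or metric is the
share of sites belonging to subgraphs whose adopted model includes it,
reported per tier and pooled across select levels.

### Partitioning and closure evaluation

One Voronoi diagram is computed over all sites (GEOS, via shapely) and
reused across levels, so coarser polygons are *exact* unions of finer ones;
cells are clipped to the study boundary (default: buffered convex hull of
the sites). Duplicate site coordinates are an input error — jitter is the
caller's responsibility. Dissolution checks the tessellation invariants
(interior-disjoint polygons, areas summing to the boundary area within
1e-6 relative) and reports clusters whose polygons are multi-part, which
after adjacency enforcement should only be detached-site singletons.

Telemetry is windowed by biological year (starting March 1; leap-day fixes
belong to the preceding year). GPS residence time uses deterministic linear
interpolation: each inter-fix segment's duration is split across polygons
in proportion to sub-segment lengths, with shared edges claimed once in
ascending cluster-id order and totals conserving elapsed time exactly. This
replaces the dynamic Brownian bridge movement model sometimes used for this
purpose: the bridge's occupancy spreading is orthogonal to the quantity
under test (the time-share semantics of closure), while linear
interpolation is deterministic and exactly conservative. Time beyond all
polygons accrues to a reserved `outside` pseudo-cluster rather than being
dropped. The home cluster is computed per bird per biological year (most
fixes for VHF, most residence time for GPS; ties to the lower cluster id);
proportions outside the home are pooled across the bird's years, and each
level reports the mean and SE (sd/√n birds) separately for VHF and GPS.

## Synthetic study systems

The generator emulates the ingredients the workflow consumes, not any real
ecosystem: group territories on a square grid of centers separated by a
configurable distance (default 30 km, comparable to dispersal-scale
separation); a group-patterned covariate whose territory means differ by Δ
(default 10) with i.i.d. Gaussian within-territory noise σ (default 1); a
pure-noise distractor covariate; uniform resistance 1 with an optional
vertical barrier band; sites drawn uniformly in disks (default radius =
separation/10) around their centers; and telemetry random walks whose whole
segments stay inside the home polygon — which makes zero-excursion closure
exact by construction even for non-convex polygons — with excursions to a
uniformly chosen neighboring polygon for a geometric(1/2)-length stay at a
configurable per-segment rate. Every generator is a pure function of
(seed, parameters).

What passing tests on these fixtures do **not** show: robustness to
real-world covariate collinearity, spatially autocorrelated noise,
irregular telemetry duty cycles, GPS error, or resistance surfaces with
realistic cost structure. The fixtures establish that the machinery is
correct, not that any particular ecological inference is.

## Numerical choices and problem sizes

Determinism everywhere: one root seed, sorted edge insertion before
Kruskal, lexicographic tie-breaks in cuts and corrections, cluster ids
relabeled by smallest member site, output CSVs sorted. Floating tolerances:
tessellation area 1e-6 relative; residence-time conservation validated at
1e-6 and rescaled exactly; segment-coverage shortfalls below 1e-9 of the
segment length are treated as float slop, not excursions.

Test and verification problem sizes are chosen to keep exhaustive oracles
exact and fast: greedy-trace comparisons on 200 random trees of ≤ 10 units,
spanning-tree enumeration on ≤ 7-node candidate graphs, independent
Dijkstra on 15×15 grids, and recovery experiments with 3–5 groups of 8
sites on 60×60-cell landscapes. These sizes are the package's own choice of
desk-scale verification conditions; the library itself has no such limits
(routing cost grows with raster cells × sites, model selection with
feature-subset count × subgraph size).

## Known limitations

- The least-cost engine is a standard lattice cost-distance; it does not
  reproduce any particular published resistance-surface formulation, and
  genetic or feature-based tier rules must be supplied as explicit
  thresholds, predicates, or precomputed tier edge lists.
- The "approximately equal-sized groups" pressure of the original SKATER is
  expressed only through the hard size window plus the balanced-cut
  tie-break; no soft balance term is added to the objective.
- AICc's parameter count (k = #features + 1) is a declared convention;
  alternative parameterizations can be swapped in one function.
- Even levels re-cluster with the inherited model under their own size
  window (rather than merely relaxing the window), which is the stricter of
  the two readings of "a progression of the clustering".
- Linear-interpolated residence time understates boundary-hugging
  occupancy relative to a movement-model-based allocation when fix
  intervals are long.
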