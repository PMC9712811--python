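"""Synthetic study systems with known group structure.

Real lek and telemetry data for species of high conservation concern are
typically access-restricted, so every downstream stage of the workflow is
exercised on synthetic landscapes generated here: a resistance surface with
an optional movement barrier, covariate rasters whose means differ between
group territories, fidelity sites drawn around well-separated group centers,
and telemetry trajectories anchored in known home polygons with a
controllable excursion rate.

All generators are pure functions of (seed, parameters): the same scenario
produces bit-identical outputs on every run.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd
from shapely.geometry import LineString, Point

from .errors import InvalidParameterError
from .raster import Raster

if TYPE_CHECKING:  # pragma: no cover
    from .partition_geometry import PartitionMap

Extent = tuple[float, float, float, float]  # (xmin, ymin, xmax, ymax), meters

DEFAULT_EXTENT: Extent = (0.0, 0.0, 100_000.0, 100_000.0)
DEFAULT_CELL_SIZE = 100.0


@dataclass
class SyntheticScenario:
    """Parameters of a synthetic study system.

    covariate_effect is the between-group difference in the informative
    covariate's territory mean (covariate units); covariate_noise is the
    within-territory standard deviation of that covariate.  barrier_cost is
    the resistance multiplier applied to a central barrier band of cells
    (1 = no barrier).  excursion_rate is the per-segment probability that a
    simulated bird leaves its home polygon for a geometric-length stay in a
    neighboring polygon.
    """

    seed: int = 0
    n_groups: int = 3
    sites_per_group: int = 20
    group_separation: float = 30_000.0     # m between neighboring group centers
    covariate_effect: float = 10.0         # Δ, between-group mean difference
    covariate_noise: float = 1.0           # σ, within-group sd
    barrier_cost: float = 1.0
    excursion_rate: float = 0.0
    site_spread: float | None = None       # within-group point spread radius; default separation/10

    def __post_init__(self) -> None:
        if self.n_groups < 1:
            raise InvalidParameterError("n_groups must be >= 1")
        if self.sites_per_group < 1:
            raise InvalidParameterError("sites_per_group must be >= 1")
        if self.covariate_noise < 0:
            raise InvalidParameterError("covariate_noise must be >= 0")
        if not math.isfinite(self.covariate_effect):
            raise InvalidParameterError("covariate_effect must be finite")
        if self.barrier_cost < 1:
            raise InvalidParameterError("barrier_cost must be >= 1")
        if not 0 <= self.excursion_rate <= 1:
            raise InvalidParameterError("excursion_rate must be in [0, 1]")

    @property
    def spread(self) -> float:
        return self.site_spread if self.site_spread is not None else self.group_separation / 10.0

    def rng(self, stream: int) -> np.random.Generator:
        """Independent deterministic substream per generator."""
        return np.random.default_rng([self.seed, stream])


def group_centers(scenario: SyntheticScenario, extent: Extent = DEFAULT_EXTENT) -> np.ndarray:
    """(n_groups, 2) territory centers on a square grid centered in the extent.

    Raises if the grid of centers (with a margin of one spread radius) does
    not fit inside the extent.
    """
    xmin, ymin, xmax, ymax = extent
    n = scenario.n_groups
    ncols = int(math.ceil(math.sqrt(n)))
    nrows = int(math.ceil(n / ncols))
    sep = scenario.group_separation
    cx, cy = (xmin + xmax) / 2.0, (ymin + ymax) / 2.0
    xs = cx + (np.arange(ncols) - (ncols - 1) / 2.0) * sep
    ys = cy + (np.arange(nrows) - (nrows - 1) / 2.0) * sep
    centers = np.array([(xs[i % ncols], ys[i // ncols]) for i in range(n)])
    margin = scenario.spread
    if (
        centers[:, 0].min() - margin < xmin
        or centers[:, 0].max() + margin > xmax
        or centers[:, 1].min() - margin < ymin
        or centers[:, 1].max() + margin > ymax
    ):
        raise InvalidParameterError(
            f"{n} groups at separation {sep} m (+ spread {margin} m) do not fit in extent {extent}"
        )
    return centers


def make_landscape(
    scenario: SyntheticScenario,
    extent: Extent = DEFAULT_EXTENT,
    cell_size: float = DEFAULT_CELL_SIZE,
) -> tuple[Raster, dict[str, Raster]]:
    """Resistance raster plus covariate rasters sharing its grid.

    The ``habitat`` covariate is group-patterned: each cell takes the mean
    Δ·g of its nearest group territory g plus i.i.d. Gaussian noise σ.  The
    ``distractor`` covariate is pure unit-variance noise with no group
    signal.  Resistance is 1 everywhere except an optional vertical barrier
    band at ``barrier_cost``.
    """
    xmin, ymin, xmax, ymax = extent
    width, height = xmax - xmin, ymax - ymin
    if width <= 0 or height <= 0:
        raise InvalidParameterError(f"extent must have positive area, got {extent}")
    if cell_size <= 0:
        raise InvalidParameterError(f"cell_size must be positive, got {cell_size}")
    ncols = int(round(width / cell_size))
    nrows = int(round(height / cell_size))
    if ncols < 1 or nrows < 1:
        raise InvalidParameterError("cell_size larger than extent")
    for span, ncells in ((width, ncols), (height, nrows)):
        if abs(ncells * cell_size - span) > 1e-6 * max(span, 1.0):
            raise InvalidParameterError(
                f"cell_size {cell_size} does not divide extent span {span} within rounding"
            )

    resistance = Raster(np.ones((nrows, ncols)), (xmin, ymin), cell_size)
    if scenario.barrier_cost > 1:
        band = max(1, int(round(0.02 * ncols)))
        mid = ncols // 2
        resistance.grid[:, mid - band // 2 : mid - band // 2 + band] = scenario.barrier_cost

    centers = group_centers(scenario, extent)
    xs, ys = resistance.cell_centers()
    d2 = np.stack([(xs - cx) ** 2 + (ys - cy) ** 2 for cx, cy in centers])
    nearest = np.argmin(d2, axis=0)
    rng = scenario.rng(stream=1)
    habitat = scenario.covariate_effect * nearest.astype(float)
    if scenario.covariate_noise > 0:
        habitat = habitat + rng.normal(0.0, scenario.covariate_noise, size=habitat.shape)
    distractor = scenario.rng(stream=2).normal(0.0, 1.0, size=habitat.shape)
    covariates = {
        "habitat": Raster(habitat, (xmin, ymin), cell_size),
        "distractor": Raster(distractor, (xmin, ymin), cell_size),
    }
    return resistance, covariates


def make_sites(scenario: SyntheticScenario, extent: Extent = DEFAULT_EXTENT) -> pd.DataFrame:
    """Fidelity sites with true group labels.

    Returns a DataFrame with columns site_id, x, y, true_group.  Sites are
    drawn uniformly in a disk of radius ``scenario.spread`` around their
    group center, so within-group spread is much smaller than the
    between-group separation.
    """
    centers = group_centers(scenario, extent)  # raises if groups do not fit
    rng = scenario.rng(stream=3)
    rows = []
    sid = 0
    for g, (cx, cy) in enumerate(centers):
        m = scenario.sites_per_group
        # uniform in disk: r = R*sqrt(u)
        r = scenario.spread * np.sqrt(rng.random(m))
        theta = rng.random(m) * 2 * np.pi
        for j in range(m):
            rows.append(
                {
                    "site_id": sid,
                    "x": cx + r[j] * np.cos(theta[j]),
                    "y": cy + r[j] * np.sin(theta[j]),
                    "true_group": g,
                }
            )
            sid += 1
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# telemetry


def _uniform_point_in(polygon, rng: np.random.Generator) -> tuple[float, float]:
    xmin, ymin, xmax, ymax = polygon.bounds
    for _ in range(1000):
        x = rng.uniform(xmin, xmax)
        y = rng.uniform(ymin, ymax)
        if polygon.covers(Point(x, y)):
            return x, y
    p = polygon.representative_point()
    return p.x, p.y


def _step_inside(polygon, x: float, y: float, step_sd: float, rng: np.random.Generator) -> tuple[float, float]:
    """Gaussian step whose whole segment stays inside the polygon.

    Keeping the straight segment (not just the endpoint) inside guarantees
    that linearly interpolated residence time never leaks out of the home
    polygon, even when dissolved cells are non-convex.  After 50 rejected
    proposals the bird stays put for this fix.
    """
    for _ in range(50):
        nx = x + rng.normal(0.0, step_sd)
        ny = y + rng.normal(0.0, step_sd)
        if polygon.covers(LineString([(x, y), (nx, ny)])):
            return nx, ny
    return x, y


def make_trajectories(
    scenario: SyntheticScenario,
    polygons: "PartitionMap",
    n_birds: int,
    fixes_per_bird: int,
    schedule: str = "gps",
    start: str = "2015-03-15T00:00:00",
    step_sd: float | None = None,
) -> pd.DataFrame:
    """Telemetry table: time-ordered random walks anchored in home polygons.

    Each bird is assigned a home polygon (round-robin over the partition's
    clusters).  Segments inside the home are reflected Gaussian steps; with
    probability ``excursion_rate`` a segment instead starts an excursion: the
    bird jumps to a uniformly chosen neighboring polygon and stays there for
    a geometric(1/2) number of fixes before returning.  GPS schedules are
    regular hourly fixes; VHF schedules have sparse exponential gaps.

    Returns a DataFrame (bird_id, timestamp, x, y, type) with attrs:
    ``home_cluster`` (bird -> cluster id), ``n_segments`` (excursion
    decision opportunities), ``n_excursions``, ``excursion_fraction``.
    """
    if not polygons.polygons:
        raise InvalidParameterError("polygon set is empty")
    if fixes_per_bird < 2:
        raise InvalidParameterError("fixes_per_bird must be >= 2")
    if schedule not in ("gps", "vhf"):
        raise InvalidParameterError(f"schedule must be 'gps' or 'vhf', got {schedule!r}")

    cluster_ids = sorted(polygons.polygons)
    rng = scenario.rng(stream=4)
    t0 = pd.Timestamp(start)
    rows = []
    home_of: dict[str, object] = {}
    n_segments = 0
    n_excursions = 0
    for b in range(n_birds):
        bird = f"bird{b:04d}"
        home_id = cluster_ids[b % len(cluster_ids)]
        home_of[bird] = home_id
        home = polygons.polygons[home_id]
        neighbors = polygons.neighbors(home_id) or [c for c in cluster_ids if c != home_id]
        sd = step_sd if step_sd is not None else math.sqrt(home.area) / 10.0
        x, y = _uniform_point_in(home, rng)
        if schedule == "gps":
            times = t0 + pd.to_timedelta(np.arange(fixes_per_bird), unit="h")
        else:
            gaps = 3600.0 + rng.exponential(3 * 86400.0, size=fixes_per_bird - 1)
            times = t0 + pd.to_timedelta(
                np.concatenate([[0.0], np.cumsum(np.round(gaps))]), unit="s"
            )
        rows.append((bird, times[0], x, y, schedule.upper()))
        away_remaining = 0
        away_poly = None
        for i in range(1, fixes_per_bird):
            if away_remaining > 0:
                away_remaining -= 1
                ax, ay = _uniform_point_in(away_poly, rng)
                rows.append((bird, times[i], ax, ay, schedule.upper()))
                continue
            n_segments += 1
            if neighbors and rng.random() < scenario.excursion_rate:
                n_excursions += 1
                away_poly = polygons.polygons[neighbors[rng.integers(len(neighbors))]]
                away_remaining = int(rng.geometric(0.5)) - 1
                ax, ay = _uniform_point_in(away_poly, rng)
                rows.append((bird, times[i], ax, ay, schedule.upper()))
            else:
                x, y = _step_inside(home, x, y, sd, rng)
                rows.append((bird, times[i], x, y, schedule.upper()))
    df = pd.DataFrame(rows, columns=["bird_id", "timestamp", "x", "y", "type"])
    df.attrs["home_cluster"] = home_of
    df.attrs["n_segments"] = n_segments
    df.attrs["n_excursions"] = n_excursions
    df.attrs["excursion_fraction"] = n_excursions / n_segments if n_segments else 0.0
    return df
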