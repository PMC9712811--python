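"""Multi-scale zonal habitat summaries around fidelity sites.

Each covariate raster is summarized in closed disks of several radii around
every site (arithmetic mean and coefficient of variation), producing one
feature per covariate × radius × statistic.  Per clustering unit the member
sites' values are aggregated by median and z-scored; columns that come out
constant are flagged so model enumeration can exclude them (a constant
attribute drives the within-group sum of squares to zero and admits no
information-criterion score).

Feature names follow ``<covariate>__r<radius>__<stat>``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InvalidParameterError
from .raster import Raster

#: radii (m) used when a configuration does not specify its own ladder;
#: endpoints follow the conventional 30–6400 m multi-scale window
DEFAULT_RADII = (30.0, 100.0, 200.0, 400.0, 800.0, 1600.0, 3200.0, 6400.0)


@dataclass
class CovariateFeature:
    covariate_name: str
    radius: float               # meters; 0 = single-cell lookup
    statistic: str              # "mean" | "cv" | "none"
    values: pd.Series           # indexed by site_id; NaN = missing

    @property
    def name(self) -> str:
        r = int(self.radius) if float(self.radius).is_integer() else self.radius
        return f"{self.covariate_name}__r{r}__{self.statistic}"


def zonal_summary(
    raster: Raster, sites: pd.DataFrame, radius: float, statistic: str
) -> CovariateFeature:
    """Summarize a raster in the closed disk of ``radius`` around each site.

    Disk membership is by cell-center inclusion: all non-nodata cells whose
    centers lie within ``radius`` of the site point contribute.  ``cv`` is
    the sample (n−1) standard deviation divided by the mean; a zero mean
    with nonzero spread, or an all-nodata disk, yields a missing value.
    ``radius`` 0 looks up the single containing cell.
    """
    if statistic not in ("mean", "cv"):
        raise InvalidParameterError(f"statistic must be 'mean' or 'cv', got {statistic!r}")
    if radius != 0 and radius < raster.cell_size / 2:
        raise InvalidParameterError(
            f"radius must be 0 or >= cell_size/2 ({raster.cell_size / 2}), got {radius}"
        )
    xs, ys = raster.cell_centers()
    valid = raster.mask()
    out = {}
    for _, row in sites.iterrows():
        sid, x, y = row["site_id"], row["x"], row["y"]
        if radius == 0:
            try:
                r, c = raster.cell_of(x, y)
            except InvalidParameterError:
                warnings.warn(f"site {sid!r} outside raster extent; value missing")
                out[sid] = np.nan
                continue
            if not valid[r, c]:
                warnings.warn(f"site {sid!r} on nodata cell; value missing")
                out[sid] = np.nan
                continue
            vals = np.array([raster.grid[r, c]])
        else:
            # restrict to the bounding window before the disk test
            r0, c0, r1, c1 = _window(raster, x, y, radius)
            if r0 >= r1 or c0 >= c1:
                warnings.warn(f"site {sid!r}: disk outside raster extent; value missing")
                out[sid] = np.nan
                continue
            wx, wy = xs[r0:r1, c0:c1], ys[r0:r1, c0:c1]
            inside = ((wx - x) ** 2 + (wy - y) ** 2 <= radius**2) & valid[r0:r1, c0:c1]
            vals = raster.grid[r0:r1, c0:c1][inside]
            if vals.size == 0:
                warnings.warn(f"site {sid!r}: disk entirely nodata; value missing")
                out[sid] = np.nan
                continue
        mean = float(vals.mean())
        if statistic == "mean":
            out[sid] = mean
        else:
            sd = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
            if mean == 0 and sd != 0:
                warnings.warn(f"site {sid!r}: zero mean with nonzero sd; cv missing")
                out[sid] = np.nan
            elif mean == 0:
                out[sid] = 0.0
            else:
                out[sid] = sd / mean
    values = pd.Series(out).reindex(sites["site_id"])
    values.index.name = "site_id"
    return CovariateFeature("cov", radius, statistic, values)


def _window(raster: Raster, x: float, y: float, radius: float) -> tuple[int, int, int, int]:
    x0, y0 = raster.origin
    cs = raster.cell_size
    c0 = max(0, int(np.floor((x - radius - x0) / cs)) - 1)
    c1 = min(raster.ncols, int(np.ceil((x + radius - x0) / cs)) + 1)
    rb0 = max(0, int(np.floor((y - radius - y0) / cs)) - 1)
    rb1 = min(raster.nrows, int(np.ceil((y + radius - y0) / cs)) + 1)
    # rows count from the top
    r0 = raster.nrows - rb1
    r1 = raster.nrows - rb0
    return max(0, r0), c0, min(raster.nrows, r1), c1


def feature_table(
    rasters: dict[str, Raster],
    sites: pd.DataFrame,
    radii=DEFAULT_RADII,
    statistics=("mean", "cv"),
) -> pd.DataFrame:
    """Site-by-feature table over every covariate × radius × statistic."""
    cols = {}
    for name, raster in sorted(rasters.items()):
        usable = [r for r in radii if r == 0 or r >= raster.cell_size / 2]
        skipped = sorted(set(radii) - set(usable))
        if skipped:
            warnings.warn(
                f"radii {skipped} below half the {name!r} cell size "
                f"({raster.cell_size}); skipped"
            )
        for radius in usable:
            for stat in statistics:
                feat = zonal_summary(raster, sites, radius, stat)
                feat.covariate_name = name
                cols[feat.name] = feat.values
    df = pd.DataFrame(cols)
    df.index.name = "site_id"
    return df


def group_median(assignment: pd.Series, values: pd.Series) -> pd.Series:
    """Median of member-site values per unit; missing members are excluded.

    An even member count takes the mean of the two central values (pandas
    convention).  A unit whose members are all missing gets a missing value
    with a warning.
    """
    assignment = assignment.reindex(values.index)
    if assignment.isna().any():
        missing = list(values.index[assignment.isna()])
        raise InvalidParameterError(f"sites without unit assignment: {missing[:5]}")
    med = values.groupby(assignment).median()
    if med.isna().any():
        warnings.warn(f"units with all-missing values: {list(med.index[med.isna()])}")
    return med


def standardize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Column-wise z-scores (sample sd, n−1); constant columns become zero.

    The names of zero-variance columns are recorded in
    ``result.attrs["constant_columns"]`` so callers can exclude them from
    model scoring.
    """
    if len(matrix) < 2:
        raise InvalidParameterError("standardize requires at least 2 units")
    mean = matrix.mean()
    sd = matrix.std(ddof=1)
    constant = sorted(sd.index[(sd == 0) | sd.isna()])
    if constant:
        warnings.warn(f"zero-variance columns set to 0: {constant}")
    safe = sd.replace(0, np.nan)
    z = (matrix - mean) / safe
    z[constant] = 0.0
    z.attrs["constant_columns"] = constant
    return z


def null_covariate(sites: pd.DataFrame, seed: int) -> CovariateFeature:
    """Random integers on [0, 1,000,000] per site (non-habitat null mode).

    Stands in for habitat information when evaluating how much the habitat
    covariates themselves contribute: a random attribute still lets the
    clustering run (a constant would give zero within-group sums of squares
    and no information-criterion score) but carries no biological signal.
    """
    rng = np.random.default_rng(seed)
    vals = pd.Series(
        rng.integers(0, 1_000_001, size=len(sites)).astype(float),
        index=pd.Index(sites["site_id"], name="site_id"),
    )
    return CovariateFeature("null", 0.0, "none", vals)
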