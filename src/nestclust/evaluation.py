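"""Telemetry-based evaluation of geographic closure.

For each cluster level, every bird is assigned a *home cluster* per
biological year (years start March 1, the onset of the breeding season):
the cluster polygon holding the most use locations (VHF) or the greatest
residence time (GPS).  The proportion of each bird's use (VHF) or time
(GPS) spent outside its home cluster, pooled across the bird's biological
years, measures how far the level's polygons are from geographic closure;
per level the mean and standard error across birds are reported.

GPS residence time is allocated by deterministic linear interpolation: each
inter-fix segment's duration is split across polygons in proportion to the
straight-line sub-segment lengths falling inside each polygon.  Movement
between fixes is thus assumed straight and at constant speed; time spent
beyond all polygons accrues to a reserved ``outside`` pseudo-cluster rather
than being dropped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely.geometry import LineString, Point

from .errors import InvalidInputError, ParseError
from .partition_geometry import PartitionMap

OUTSIDE = "outside"


def split_biological_years(fixes: pd.DataFrame) -> pd.Series:
    """Biological year per fix: the year of the most recent March 1.

    A fix on 2015-02-28 belongs to biological year 2014; 2015-03-01 starts
    biological year 2015 (leap-day fixes fall in the preceding year).
    """
    ts = pd.to_datetime(fixes["timestamp"], errors="coerce")
    bad = ts.isna()
    if bad.any():
        rows = list(fixes.index[bad])
        raise ParseError(f"unparseable timestamps at rows {rows[:10]}")
    return (ts.dt.year - (ts.dt.month < 3).astype(int)).rename("biological_year")


def _point_cluster(x: float, y: float, polygons: PartitionMap):
    p = Point(x, y)
    for cid in sorted(polygons.polygons, key=str):
        if polygons.polygons[cid].covers(p):
            return cid
    return OUTSIDE


def residence_time(trajectory: pd.DataFrame, polygons: PartitionMap) -> pd.Series:
    """Seconds per cluster for one bird's time-ordered GPS fixes.

    Each segment's duration is split among polygons proportionally to the
    sub-segment lengths inside each; the totals sum exactly (to floating
    tolerance) to the elapsed time between the first and last fix.  Shared
    polygon edges are claimed once, in ascending cluster-id order.
    """
    traj = trajectory.sort_values("timestamp") if not trajectory["timestamp"].is_monotonic_increasing else trajectory
    ts = pd.to_datetime(traj["timestamp"])
    if len(traj) < 2:
        raise InvalidInputError("residence_time requires at least 2 fixes")
    if (ts.diff().dropna() <= pd.Timedelta(0)).any():
        raise InvalidInputError("timestamps must be strictly increasing within a bird")
    xs, ys = traj["x"].to_numpy(float), traj["y"].to_numpy(float)
    seconds = ts.astype("int64").to_numpy() / 1e9
    totals: dict = {cid: 0.0 for cid in polygons.polygons}
    totals[OUTSIDE] = 0.0
    ordered = sorted(polygons.polygons, key=str)
    warned = False
    for i in range(len(traj) - 1):
        dur = seconds[i + 1] - seconds[i]
        seg = LineString([(xs[i], ys[i]), (xs[i + 1], ys[i + 1])])
        if seg.length == 0:
            totals[_point_cluster(xs[i], ys[i], polygons)] += dur
            continue
        remaining = seg
        covered = 0.0
        for cid in ordered:
            if remaining.is_empty:
                break
            part = remaining.intersection(polygons.polygons[cid])
            if not part.is_empty and part.length > 0:
                totals[cid] += dur * part.length / seg.length
                covered += part.length
                remaining = remaining.difference(polygons.polygons[cid])
        shortfall = seg.length - covered
        if shortfall > 1e-9 * seg.length:  # genuine uncovered stretch, not float slop
            totals[OUTSIDE] += dur * shortfall / seg.length
            if not warned:
                warned = True
                warnings.warn("trajectory leaves all polygons; time booked to 'outside'")
    # exact conservation: rescale out the accumulated floating slack
    out = pd.Series(totals)
    elapsed = seconds[-1] - seconds[0]
    slack = elapsed - out.sum()
    if abs(slack) > 1e-6 * max(elapsed, 1.0):
        raise InvalidInputError("residence time does not conserve elapsed time")
    if out.sum() > 0:
        out *= elapsed / out.sum()
    return out


def assign_home_cluster(
    trajectory: pd.DataFrame, polygons: PartitionMap
) -> dict:
    """Home cluster per biological year: most fixes (VHF) or most residence
    time (GPS); ties go to the lower cluster id."""
    if trajectory.empty:
        raise InvalidInputError("empty trajectory")
    traj = trajectory.copy()
    traj["biological_year"] = split_biological_years(traj)
    kind = traj["type"].iloc[0].upper()
    homes = {}
    for year, grp in traj.groupby("biological_year"):
        if kind == "GPS" and len(grp) >= 2:
            weights = residence_time(grp, polygons)
        else:
            counts: dict = {}
            for x, y in zip(grp["x"], grp["y"]):
                cid = _point_cluster(x, y, polygons)
                counts[cid] = counts.get(cid, 0) + 1
            weights = pd.Series(counts)
        weights = weights.drop(OUTSIDE, errors="ignore")
        if weights.empty or weights.sum() == 0:
            homes[year] = OUTSIDE
            continue
        top = weights[weights == weights.max()]
        homes[year] = sorted(top.index, key=str)[0]
    return homes


@dataclass
class ClosureResult:
    level_index: int
    per_bird: pd.DataFrame        # bird_id, type, prop_outside
    summary: pd.DataFrame         # type, n_birds, mean_prop_outside, se


def closure_summary(
    trajectories: pd.DataFrame, partitions: list[PartitionMap]
) -> list[ClosureResult]:
    """Per-level closure evaluation for a telemetry table.

    Per bird: the home cluster is found per biological year; the proportion
    of fixes (VHF) or time (GPS) outside the home cluster is pooled across
    the bird's years.  Per level and telemetry type: mean and standard
    error (sd/√n_birds) across birds.  GPS birds with a single fix are
    excluded from the time metric with a warning.
    """
    if trajectories.empty:
        raise InvalidInputError("no telemetry provided")
    results = []
    for pm in partitions:
        rows = []
        for bird, traj in trajectories.groupby("bird_id"):
            traj = traj.sort_values("timestamp")
            kind = traj["type"].iloc[0].upper()
            if kind == "GPS" and len(traj) < 2:
                warnings.warn(f"GPS bird {bird!r} has a single fix; excluded from time metric")
                continue
            homes = assign_home_cluster(traj, pm)
            years = split_biological_years(traj)
            outside = 0.0
            total = 0.0
            for year, grp in traj.groupby(years):
                home = homes[year]
                if kind == "GPS":
                    rt = residence_time(grp, pm) if len(grp) >= 2 else pd.Series(dtype=float)
                    total += rt.sum()
                    outside += rt.drop(home, errors="ignore").sum()
                else:
                    for x, y in zip(grp["x"], grp["y"]):
                        total += 1
                        if _point_cluster(x, y, pm) != home:
                            outside += 1
            prop = outside / total if total > 0 else np.nan
            rows.append({"bird_id": bird, "type": kind, "prop_outside": prop})
        per_bird = pd.DataFrame(rows)
        summary_rows = []
        for kind, grp in per_bird.groupby("type"):
            vals = grp["prop_outside"].dropna()
            n = len(vals)
            mean = float(vals.mean()) if n else np.nan
            se = float(vals.std(ddof=1) / np.sqrt(n)) if n > 1 else np.nan
            summary_rows.append(
                {"type": kind, "n_birds": n, "mean_prop_outside": mean, "se": se}
            )
        results.append(
            ClosureResult(
                level_index=pm.level_index,
                per_bird=per_bird,
                summary=pd.DataFrame(summary_rows),
            )
        )
    return results
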