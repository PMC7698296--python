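"""Visit detection: classifying GPS fixes and aggregating visit days.

A fix is a visit to a farm area when all three criteria hold:

* the fix lies inside the merged buffer polygon (boundary counts as in),
* altitude above ground (GPS altitude minus interpolated DEM elevation)
  is strictly below 25 m,
* instantaneous speed is strictly below 2 m/s.

Qualifying fixes collapse to one visit day per (bird, farm area, calendar
date).  Day-level tracking coverage drives the eligibility rule: a
bird-semester enters the analyses only when every month of the semester
has data on at least 15 days.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely import STRtree
from shapely.geometry import Point

from .dem import AsciiGrid
from .geometry import FarmArea
from .periods import Semester

__all__ = [
    "VisitThresholds",
    "classify_fix",
    "classify_fixes",
    "aggregate_visit_days",
    "coverage_and_eligibility",
    "visit_distance_summary",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class VisitThresholds:
    max_altitude_agl_m: float = 25.0  # strict: altitude above ground < 25
    max_speed_ms: float = 2.0  # strict: speed < 2


def classify_fixes(
    fixes: pd.DataFrame,
    farm_areas: list[FarmArea],
    dem: AsciiGrid,
    thresholds: VisitThresholds = VisitThresholds(),
) -> pd.Series:
    """Vectorized fix classification.

    Returns a Series aligned with ``fixes`` holding the containing
    ``area_id`` for qualifying fixes and ``None`` elsewhere.  Fixes
    outside the DEM extent are excluded and counted in the log.
    """
    result = pd.Series([None] * len(fixes), index=fixes.index, dtype=object)
    if not len(fixes) or not farm_areas:
        return result
    x = fixes["x"].to_numpy(float)
    y = fixes["y"].to_numpy(float)
    covered = dem.covers(x, y)
    n_out = int((~covered).sum())
    if n_out:
        log.warning("%d fixes outside DEM extent excluded from classification", n_out)

    speed_ok = fixes["speed_ms"].to_numpy(float) < thresholds.max_speed_ms
    cand = covered & speed_ok
    if not cand.any():
        return result
    idx = np.flatnonzero(cand)
    agl = fixes["altitude_m"].to_numpy(float)[idx] - dem.elevation_at(x[idx], y[idx])
    idx = idx[agl < thresholds.max_altitude_agl_m]
    if not len(idx):
        return result

    tree = STRtree([a.polygon for a in farm_areas])
    pts = [Point(x[i], y[i]) for i in idx]
    # boundary counts as inside: covered_by, not within
    qi, ti = tree.query(pts, predicate="covered_by")
    positional = fixes.index.to_numpy()
    for q, t in zip(qi, ti):
        result.loc[positional[idx[q]]] = farm_areas[t].area_id
    return result


def classify_fix(
    fix,
    farm_areas: list[FarmArea],
    dem: AsciiGrid,
    thresholds: VisitThresholds = VisitThresholds(),
) -> str | None:
    """Classify a single fix; returns the containing area_id or None.

    ``fix`` is any mapping with x, y, altitude_m, speed_ms.
    """
    if not dem.covers(fix["x"], fix["y"]):
        raise ValueError("fix outside DEM extent")
    if fix["speed_ms"] >= thresholds.max_speed_ms:
        return None
    agl = fix["altitude_m"] - dem.elevation_at(fix["x"], fix["y"])
    if agl >= thresholds.max_altitude_agl_m:
        return None
    p = Point(fix["x"], fix["y"])
    for area in farm_areas:
        if area.polygon.covers(p):
            return area.area_id
    return None


def aggregate_visit_days(
    fixes: pd.DataFrame,
    farm_areas: list[FarmArea],
    dem: AsciiGrid,
    thresholds: VisitThresholds = VisitThresholds(),
) -> pd.DataFrame:
    """Detect visits and collapse them to unique (bird, area, date) days.

    Returns a sorted DataFrame with columns bird_id, area_id, date.
    The result is a pure function of the fix set: fix order is irrelevant.
    """
    area_ids = classify_fixes(fixes, farm_areas, dem, thresholds)
    hit = area_ids.notna()
    if not hit.any():
        return pd.DataFrame(columns=["bird_id", "area_id", "date"])
    sub = fixes.loc[hit, ["bird_id", "timestamp"]].copy()
    sub["area_id"] = area_ids[hit]
    sub["date"] = pd.to_datetime(sub["timestamp"], utc=True).dt.date
    out = (
        sub[["bird_id", "area_id", "date"]]
        .drop_duplicates()
        .sort_values(["bird_id", "area_id", "date"])
        .reset_index(drop=True)
    )
    return out


def coverage_and_eligibility(
    fixes: pd.DataFrame,
    semesters: list[Semester],
    min_days_per_month: int = 15,
) -> pd.DataFrame:
    """Per bird-semester tracking coverage and the 15-days-per-month rule.

    A calendar day counts as "with data" when the bird has at least one
    fix that date.  A bird-semester is eligible iff *every* month of the
    semester has at least ``min_days_per_month`` data days; its binomial
    denominator ``n_days`` is the total number of data days in the
    semester.
    """
    if len(fixes):
        ts = pd.to_datetime(fixes["timestamp"], utc=True)
        days = pd.DataFrame(
            {"bird_id": fixes["bird_id"].to_numpy(), "date": ts.dt.date}
        ).drop_duplicates()
    else:
        days = pd.DataFrame(columns=["bird_id", "date"])
    birds = sorted(days["bird_id"].unique())
    rows = []
    for bird in birds:
        bd = days.loc[days["bird_id"] == bird, "date"]
        by_month: dict[tuple[int, int], int] = {}
        for d in bd:
            key = (d.year, d.month)
            by_month[key] = by_month.get(key, 0) + 1
        for sem in semesters:
            month_days = [by_month.get(m, 0) for m in sem.months]
            n_days = sum(
                1 for d in bd if sem.start <= d <= sem.end
            )
            rows.append(
                {
                    "bird_id": bird,
                    "semester": sem.label,
                    "n_days": n_days,
                    "eligible": all(c >= min_days_per_month for c in month_days),
                }
            )
    return pd.DataFrame(rows, columns=["bird_id", "semester", "n_days", "eligible"])


def visit_distance_summary(
    fixes: pd.DataFrame,
    area_ids: pd.Series,
    farm_points: np.ndarray,
) -> tuple[float, float]:
    """Mean and SD of the distance from each qualifying fix to the nearest
    original farm point (descriptive summary of detector behaviour).

    ``area_ids`` is the output of :func:`classify_fixes`; ``farm_points``
    is an (n, 2) array of the raw registry points.
    """
    hit = area_ids.notna()
    if not hit.any():
        raise ValueError("no qualifying fixes")
    from scipy.spatial import cKDTree

    pts = fixes.loc[hit, ["x", "y"]].to_numpy(float)
    d, _ = cKDTree(np.asarray(farm_points, float)).query(pts)
    return float(np.mean(d)), float(np.std(d))
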