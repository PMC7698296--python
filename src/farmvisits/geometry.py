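"""Farm areas and farm-level spatial covariates.

The spatial unit of analysis is the *farm area*: the union of buffer disks
(default radius 180 m) around one or more farm points whose buffers
overlap.  Two farms belong to the same area exactly when their points are
strictly closer than twice the buffer radius; overlap is transitive, so
areas are the connected components of that proximity graph.

All coordinates are planar metric (projected).  Covariates are measured
from the centroid of the merged buffer polygon.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import shapely
from scipy.spatial import cKDTree
from shapely.geometry import Point, Polygon
from shapely.ops import unary_union

from .dem import AsciiGrid

__all__ = [
    "Farm",
    "FarmArea",
    "Landscape",
    "CovariateRow",
    "BirdContext",
    "build_farm_areas",
    "nearest_distance",
    "farm_covariates",
]

#: quarter-circle segment count for buffer disks: 4 * 16 = 64 segments per
#: circle, giving sub-metre error at a 180 m radius.
BUFFER_QUAD_SEGS = 16

DEFAULT_BUFFER_RADIUS_M = 180.0


@dataclass
class Farm:
    """A registered livestock holding: a point plus per-semester herd counts."""

    farm_id: str
    x: float
    y: float
    herd: Mapping[str, int]  # semester label -> goat+sheep head count
    disposal_answer: int | None = None  # 1 abandon, 0 not, None unknown
    active: Mapping[str, bool] | None = None  # semester label -> active flag

    def __post_init__(self) -> None:
        if not (np.isfinite(self.x) and np.isfinite(self.y)):
            raise ValueError(f"farm {self.farm_id}: non-finite coordinates")
        if any(v < 0 for v in self.herd.values()):
            raise ValueError(f"farm {self.farm_id}: negative herd size")

    def is_active(self, semester: str) -> bool:
        if self.active is None:
            return True
        return bool(self.active.get(semester, True))


@dataclass
class FarmArea:
    """A merged buffer polygon grouping one or more farms."""

    area_id: str
    members: tuple[str, ...]
    polygon: Polygon
    centroid: tuple[float, float]
    herd: dict[str, int]  # per-semester sum over members
    carcass: float | None = None  # observed 0/1 or imputed probability
    member_points: tuple[tuple[float, float], ...] = field(default_factory=tuple)

    def is_active(self, semester: str, farms_by_id: Mapping[str, Farm] | None = None) -> bool:
        if farms_by_id is None:
            return True
        return any(farms_by_id[m].is_active(semester) for m in self.members)


@dataclass
class Landscape:
    """Static layers used for distance covariates."""

    roads: list  # shapely LineStrings
    urban: list  # shapely Polygons
    dump: list  # shapely Points
    feeding_stations: list  # shapely Points
    dem: AsciiGrid | None = None

    @property
    def hpfp(self) -> list:
        """Highly predictable feeding places: dump plus feeding stations."""
        return list(self.dump) + list(self.feeding_stations)


@dataclass
class BirdContext:
    """Per bird-semester quantities needed for individual-level covariates."""

    bird_id: str
    semester: str
    territorial: bool
    own_nest: tuple[float, float] | None
    occupied_nests: Sequence[tuple[float, float]]  # all occupied that semester
    k50_polygons: object | None = None  # shapely (Multi)Polygon
    area_k95_km2: float | None = None
    sex: str | None = None  # "M" / "F"
    age: float | None = None
    success: int | None = None


@dataclass
class CovariateRow:
    """One farm-(bird)-semester set of fixed-effect covariates, in metres."""

    dist_hpfp: float
    dist_urb: float
    dist_road: float
    dist_dump: float
    dist_afs: float
    goat_sheep: float
    carcass: float | None = None
    breeding: int | None = None
    dist_terr: float | None = None
    dist_k50: float | None = None
    dist_nest: float | None = None
    area_k95: float | None = None
    sex: str | None = None
    age: float | None = None
    success: int | None = None

    def __post_init__(self) -> None:
        for name in ("dist_hpfp", "dist_urb", "dist_road", "dist_dump", "dist_afs"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.carcass is not None and not (0.0 <= self.carcass <= 1.0):
            raise ValueError("carcass must lie in [0, 1]")


def _union_find(n: int, pairs: Iterable[tuple[int, int]]) -> np.ndarray:
    parent = np.arange(n)

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for a, b in pairs:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra
    return np.array([find(i) for i in range(n)])


def build_farm_areas(
    farms: Sequence[Farm],
    radius_m: float = DEFAULT_BUFFER_RADIUS_M,
) -> list[FarmArea]:
    """Group farms into merged buffer areas.

    Farms are partitioned into connected components of the graph linking
    pairs strictly closer than ``2 * radius_m``; each component becomes one
    :class:`FarmArea` whose polygon is the union of the member disks.  The
    partition does not depend on input order: members are sorted and area
    ids are assigned by the south-west-most member point.
    """
    if radius_m <= 0:
        raise ValueError("radius_m must be positive")
    ids = [f.farm_id for f in farms]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate farm_id in registry")
    if not farms:
        return []
    pts = np.array([[f.x, f.y] for f in farms])
    uniq = {}
    for i, p in enumerate(map(tuple, pts)):
        if p in uniq:
            warnings.warn(
                f"coincident farms {ids[uniq[p]]} and {ids[i]}; they will merge",
                stacklevel=2,
            )
        else:
            uniq[p] = i

    tree = cKDTree(pts)
    # strict inequality at the threshold: distance == 2r does not merge
    pairs = [
        (i, j)
        for i, j in tree.query_pairs(r=2.0 * radius_m, output_type="ndarray")
        if np.hypot(*(pts[i] - pts[j])) < 2.0 * radius_m
    ]
    labels = _union_find(len(farms), pairs)

    areas: list[FarmArea] = []
    for root in np.unique(labels):
        idx = sorted(np.flatnonzero(labels == root), key=lambda i: ids[i])
        disks = [Point(pts[i]).buffer(radius_m, quad_segs=BUFFER_QUAD_SEGS) for i in idx]
        poly = unary_union(disks)
        herd: dict[str, int] = {}
        for i in idx:
            for sem, h in farms[i].herd.items():
                herd[sem] = herd.get(sem, 0) + int(h)
        carcass_vals = [farms[i].disposal_answer for i in idx if farms[i].disposal_answer is not None]
        # any member abandoning makes the merged area a potential food source
        carcass = float(max(carcass_vals)) if carcass_vals else None
        areas.append(
            FarmArea(
                area_id="",
                members=tuple(ids[i] for i in idx),
                polygon=poly,
                centroid=(poly.centroid.x, poly.centroid.y),
                herd=herd,
                carcass=carcass,
                member_points=tuple((pts[i][0], pts[i][1]) for i in idx),
            )
        )
    areas.sort(key=lambda a: min(a.member_points))
    for k, a in enumerate(areas):
        a.area_id = f"FA{k + 1:04d}"
    return areas


def nearest_distance(point: tuple[float, float], features: Sequence, label: str = "feature") -> float:
    """Euclidean distance from ``point`` to the nearest feature.

    Points inside a polygon feature are at distance 0.
    """
    if not features:
        raise ValueError(f"no {label} features available for distance covariate")
    p = Point(point)
    return float(min(p.distance(f) for f in features))


def farm_covariates(
    area: FarmArea,
    landscape: Landscape,
    semester: str,
    breeding: int | None = None,
    bird: BirdContext | None = None,
) -> CovariateRow:
    """Distance and context covariates for one farm area (and optionally
    one bird) in one semester.

    ``dist_terr`` is the distance to the nearest *occupied* nest, excluding
    the focal bird's own nest for territorial birds.  ``dist_k50`` is 0
    when the centroid lies inside a core-area polygon.
    """
    c = area.centroid
    row = CovariateRow(
        dist_hpfp=nearest_distance(c, landscape.hpfp, "HPFP"),
        dist_urb=nearest_distance(c, landscape.urban, "urban"),
        dist_road=nearest_distance(c, landscape.roads, "road"),
        dist_dump=nearest_distance(c, landscape.dump, "dump"),
        dist_afs=nearest_distance(c, landscape.feeding_stations, "feeding station"),
        goat_sheep=float(area.herd.get(semester, 0)),
        carcass=area.carcass,
        breeding=breeding,
    )
    if bird is None:
        return row

    if bird.territorial and bird.own_nest is None:
        raise ValueError(f"territorial bird {bird.bird_id} ({bird.semester}) has no nest")
    nests = list(bird.occupied_nests)
    if bird.territorial and bird.own_nest is not None:
        nests = [n for n in nests if not np.allclose(n, bird.own_nest)]
    if nests:
        row.dist_terr = nearest_distance(c, [Point(n) for n in nests], "occupied nest")
    if bird.k50_polygons is not None:
        row.dist_k50 = float(Point(c).distance(bird.k50_polygons))
    if bird.territorial and bird.own_nest is not None:
        row.dist_nest = float(Point(c).distance(Point(bird.own_nest)))
        row.success = bird.success
    row.area_k95 = bird.area_k95_km2
    row.sex = bird.sex
    row.age = bird.age
    return row
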