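"""Synthetic study system with fully known ground truth.

The generator emulates the empirical setting end to end: a semi-arid
island-like extent with clustered livestock farms (lognormal herd sizes),
roads, urban areas, one garbage dump and supplementary feeding stations
(jointly the highly predictable feeding places), and a smooth DEM; a
roster of GPS-tagged birds (territorial holders with nests and
non-territorial floaters); carcass-disposal behaviour drawn from a known
logistic model with only a fraction of farms "interviewed"; and farm
visits drawn from a known binomial mixed model (farm, semester and bird
random intercepts) that are then rendered into GPS fixes.

Rendering is adversarial by construction: every true visit day yields at
least one fix satisfying all three visit criteria, every background fix
is in fast flight (so it can never qualify), and decoy fixes over farms
violate exactly one criterion each (high pass, fast transit, or a
near-miss just outside the polygon).  Visit detection applied to the
rendered tracks must therefore return exactly the true visit-day set.

Defaults mirror the empirical study scale: 318 farms, 45 birds, seven
semesters, 5-minute fixes.  Tests and demos pass smaller configurations.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit
from shapely import STRtree
from shapely.geometry import LineString, Point, Polygon

from .dem import AsciiGrid
from .geometry import Farm, FarmArea, Landscape, build_farm_areas
from .periods import Semester, semester_range

__all__ = [
    "SimConfig",
    "GroundTruth",
    "SimulatedDataset",
    "simulate_landscape",
    "simulate_disposal",
    "simulate_visit_counts",
    "render_tracks",
    "simulate_dataset",
]


@dataclass(frozen=True)
class SimConfig:
    seed: int = 0
    extent: tuple[float, float, float, float] = (0.0, 0.0, 40_000.0, 30_000.0)
    n_farms: int = 318
    n_birds: int = 45
    n_semesters: int = 7
    first_semester: str = "2013-S2"
    #: lognormal (mu, sigma) of per-farm herd size, heads
    herd_size_lognormal_params: tuple[float, float] = (5.2, 1.0)
    #: logit-scale coefficients on z-scored predictors; abandonment rises
    #: with distance to urban areas and to the dump
    disposal_true_coefficients: dict = field(
        default_factory=lambda: {
            "(Intercept)": 0.4,
            "dist_dump": 0.8,
            "dist_afs": 0.0,
            "dist_road": 0.0,
            "goat_sheep": 0.0,
            "dist_urb": 1.0,
        }
    )
    #: fraction of farms with a known (interview) disposal answer
    known_disposal_fraction: float = 0.3
    #: logit-scale visit-model coefficients on z-scored covariates
    visit_true_coefficients: dict = field(
        default_factory=lambda: {
            "(Intercept)": -4.41,
            "goat_sheep": 0.44,
            "carcass": 0.56,
            "dist_road": 0.60,
            "dist_hpfp": -0.86,
            "breeding": 0.49,
            "breeding:dist_hpfp": 0.31,
        }
    )
    #: (farm, semester, bird) random-intercept SDs on the logit scale
    random_effect_sds: tuple[float, float, float] = (0.5, 0.3, 0.4)
    fix_interval_s: int = 300
    #: expected decoys per bird-day: (high-altitude pass, fast transit,
    #: near-miss outside the polygon)
    decoy_rates: tuple[float, float, float] = (0.5, 0.5, 0.2)
    buffer_radius_m: float = 180.0
    n_farm_clusters: int = 8
    fraction_territorial: float = 0.5
    movement_radius_m: float = 10_000.0
    hours_active: float = 10.0
    #: fraction of semester days with GPS data per bird
    tracked_day_fraction: float = 1.0
    #: fraction of bird-semesters degraded to one 14-day month (ineligible)
    dropout_bird_fraction: float = 0.1
    inactive_farm_fraction: float = 0.05

    def __post_init__(self) -> None:
        xmin, ymin, xmax, ymax = self.extent
        if not (xmax > xmin and ymax > ymin):
            raise ValueError("extent must be strictly positive")
        if any(s < 0 for s in self.random_effect_sds):
            raise ValueError("random-effect SDs must be >= 0")
        if not (1 <= self.fix_interval_s <= 1200):
            raise ValueError("fix_interval_s must lie in 1..1200 s")

    @property
    def semesters(self) -> list[Semester]:
        return semester_range(Semester.from_label(self.first_semester), self.n_semesters)


@dataclass
class GroundTruth:
    true_visit_days: set  # {(bird_id, area_id, iso date)}
    true_disposal: pd.Series  # per farm_id, 0/1
    known_mask: pd.Series  # per farm_id, bool
    realized_random_effects: dict  # factor -> {level: value}
    true_coefficients: dict
    design: pd.DataFrame | None = None  # the generative visit design rows


@dataclass
class SimulatedDataset:
    config: SimConfig
    farms: pd.DataFrame
    farm_objects: list[Farm]
    farm_areas: list[FarmArea]
    landscape: Landscape
    dem: AsciiGrid
    birds: pd.DataFrame
    fixes: pd.DataFrame
    truth: GroundTruth


def simulate_landscape(config: SimConfig):
    """Farm registry, landscape layers, and DEM.

    Farms follow a clustered (Thomas-like) point process; herd sizes are
    lognormal per farm with mild per-semester variation.  Returns
    ``(farms_df, landscape, dem)``.
    """
    rng = np.random.default_rng(config.seed)
    xmin, ymin, xmax, ymax = config.extent
    lx, ly = xmax - xmin, ymax - ymin
    if config.n_farms > 0 and lx * ly < config.n_farms * 1e4:
        raise ValueError(
            f"extent too small to place {config.n_farms} farms without coincident points"
        )
    semesters = [s.label for s in config.semesters]

    # clustered farm placement with a 10 m minimum separation; the
    # interior margin keeps buffer polygons and near-miss decoys on the DEM
    pts: list[tuple[float, float]] = []
    if config.n_farms > 0:
        margin = 0.05 * min(lx, ly)
        centers = rng.uniform(
            [xmin + margin, ymin + margin], [xmax - margin, ymax - margin],
            size=(config.n_farm_clusters, 2),
        )
        sd = 0.08 * min(lx, ly)
        edge = config.buffer_radius_m + 120.0
        while len(pts) < config.n_farms:
            c = centers[rng.integers(len(centers))]
            p = c + rng.normal(0.0, sd, 2)
            if not (xmin + edge <= p[0] <= xmax - edge and ymin + edge <= p[1] <= ymax - edge):
                continue
            if any((p[0] - q[0]) ** 2 + (p[1] - q[1]) ** 2 < 100.0 for q in pts):
                continue
            pts.append((float(p[0]), float(p[1])))

    base_herd = np.maximum(
        1, np.round(rng.lognormal(*config.herd_size_lognormal_params, size=len(pts)))
    )
    rows = []
    for i, (x, y) in enumerate(pts):
        row = {"farm_id": f"F{i + 1:04d}", "x": x, "y": y}
        for s in semesters:
            row[f"herd_{s}"] = int(max(1, round(base_herd[i] * rng.uniform(0.9, 1.1))))
        row["disposal_answer"] = ""
        rows.append(row)
    farms_df = pd.DataFrame(
        rows, columns=["farm_id", "x", "y", *(f"herd_{s}" for s in semesters), "disposal_answer"]
    )

    # roads: three polylines crossing the extent
    roads = [
        LineString([(xmin, ymin + 0.3 * ly), (xmax, ymin + 0.55 * ly)]),
        LineString([(xmin + 0.4 * lx, ymin), (xmin + 0.55 * lx, ymax)]),
        LineString([(xmin, ymin + 0.8 * ly), (xmax, ymin + 0.75 * ly)]),
    ]
    urban = [
        _square(xmin + 0.2 * lx, ymin + 0.25 * ly, 1200.0),
        _square(xmin + 0.7 * lx, ymin + 0.65 * ly, 900.0),
    ]
    dump = [Point(xmin + 0.35 * lx, ymin + 0.6 * ly)]
    feeding = [
        Point(xmin + 0.6 * lx, ymin + 0.3 * ly),
        Point(xmin + 0.8 * lx, ymin + 0.8 * ly),
    ]

    cell = 200.0
    ncols = int(math.ceil(lx / cell))
    nrows = int(math.ceil(ly / cell))
    xs = xmin + (np.arange(ncols) + 0.5) * cell
    ys = ymin + (np.arange(nrows) + 0.5) * cell
    gx, gy = np.meshgrid(xs, ys)
    elev = (
        180.0
        + 120.0 * np.sin(2.2 * np.pi * (gx - xmin) / lx) * np.cos(1.7 * np.pi * (gy - ymin) / ly)
        + 0.004 * (gx - xmin)
    )
    dem = AsciiGrid(values=elev[::-1], xll=xmin, yll=ymin, cellsize=cell)

    landscape = Landscape(roads=roads, urban=urban, dump=dump, feeding_stations=feeding, dem=dem)
    return farms_df, landscape, dem


def _square(cx: float, cy: float, half: float) -> Polygon:
    return Polygon(
        [(cx - half, cy - half), (cx + half, cy - half), (cx + half, cy + half), (cx - half, cy + half)]
    )


def disposal_predictor_table(farms_df: pd.DataFrame, landscape: Landscape, semester: str) -> pd.DataFrame:
    """Raw-unit predictors of the disposal model, per farm point."""
    out = pd.DataFrame({"farm_id": farms_df["farm_id"]})
    pts = [Point(x, y) for x, y in zip(farms_df["x"], farms_df["y"])]
    out["dist_dump"] = [min(p.distance(f) for f in landscape.dump) for p in pts]
    out["dist_afs"] = [min(p.distance(f) for f in landscape.feeding_stations) for p in pts]
    out["dist_road"] = [min(p.distance(f) for f in landscape.roads) for p in pts]
    out["dist_urb"] = [min(p.distance(f) for f in landscape.urban) for p in pts]
    out["goat_sheep"] = farms_df[f"herd_{semester}"].to_numpy(float)
    return out


def simulate_disposal(
    predictors: pd.DataFrame,
    coefficients: dict,
    seed: int,
    known_fraction: float = 0.3,
) -> tuple[pd.Series, pd.Series]:
    """Bernoulli disposal answers from a logit-linear model on z-scored
    predictors, plus a "known" (interviewed) mask.

    Returns ``(answers, known)`` indexed like ``predictors``.
    """
    rng = np.random.default_rng(seed)
    terms = [t for t in coefficients if t != "(Intercept)"]
    missing = [t for t in terms if t not in predictors.columns]
    if missing:
        raise ValueError(f"missing disposal predictor(s): {missing}")
    eta = np.full(len(predictors), float(coefficients.get("(Intercept)", 0.0)))
    for t in terms:
        v = predictors[t].to_numpy(float)
        sd = v.std()
        z = (v - v.mean()) / sd if sd > 0 else np.zeros_like(v)
        eta += coefficients[t] * z
    answers = pd.Series(rng.binomial(1, expit(eta)), index=predictors.index)
    known = pd.Series(rng.random(len(predictors)) < known_fraction, index=predictors.index)
    return answers, known


def simulate_visit_counts(
    design: pd.DataFrame,
    coefficients: dict,
    random_effect_sds: dict,
    seed: int,
) -> tuple[pd.Series, dict]:
    """Binomial visit numerators from a known mixed model.

    ``design`` needs a positive ``denominator`` column, one z-scored
    column per main-effect coefficient (interactions named ``a:b`` are
    formed as products), and one grouping column per entry of
    ``random_effect_sds``.  Realized random-effect values are returned
    for ground-truth bookkeeping.
    """
    rng = np.random.default_rng(seed)
    design = design[design["denominator"] > 0]
    eta = np.full(len(design), float(coefficients.get("(Intercept)", 0.0)))
    for term, beta in coefficients.items():
        if term == "(Intercept)":
            continue
        if ":" in term:
            a, b = term.split(":")
            v = design[a].to_numpy(float) * design[b].to_numpy(float)
        else:
            v = design[term].to_numpy(float)
        eta += beta * v
    realized: dict[str, dict] = {}
    for factor, sd in random_effect_sds.items():
        levels = pd.unique(design[factor])
        u = dict(zip(levels, rng.normal(0.0, sd, len(levels))))
        realized[factor] = u
        eta += design[factor].map(u).to_numpy(float)
    den = design["denominator"].to_numpy(int)
    numerators = pd.Series(rng.binomial(den, expit(eta)), index=design.index)
    return numerators, realized


def render_tracks(
    true_visit_days: set,
    tracked_days: dict,
    centers: dict,
    farm_areas: list[FarmArea],
    dem: AsciiGrid,
    config: SimConfig,
    seed: int,
) -> pd.DataFrame:
    """Render true visit days, decoys, and background flight into a fix
    table.

    ``tracked_days`` maps bird_id -> sorted list of dates with data;
    ``centers`` maps (bird_id, semester_label) -> activity centre.
    Background fixes are fast flight (speed 6-15 m/s), so only the
    deliberately rendered visit fixes can satisfy all three criteria.
    """
    rng = np.random.default_rng(seed)
    areas_by_id = {a.area_id: a for a in farm_areas}
    tree = STRtree([a.polygon for a in farm_areas]) if farm_areas else None
    visits_by_bird_day: dict[tuple[str, dt.date], list[str]] = {}
    # sets iterate in a process-dependent order; sort for reproducibility
    for bird_id, area_id, date in sorted(true_visit_days):
        visits_by_bird_day.setdefault((bird_id, date), []).append(area_id)

    n_slots = max(2, int(config.hours_active * 3600 / config.fix_interval_s))
    rate_alt, rate_fast, rate_miss = config.decoy_rates
    records: list[tuple] = []

    for bird_id in sorted(tracked_days):
        for date in tracked_days[bird_id]:
            sem = Semester(date.year, 1 if date.month <= 6 else 2).label
            cx, cy = centers[(bird_id, sem)]
            t0 = dt.datetime(date.year, date.month, date.day, 8, 0, tzinfo=dt.timezone.utc)
            slots = [t0 + dt.timedelta(seconds=i * config.fix_interval_s) for i in range(n_slots)]

            special: list[tuple] = []  # (x, y, agl, speed)
            for area_id in visits_by_bird_day.get((bird_id, date), []):
                area = areas_by_id[area_id]
                for _ in range(rng.integers(1, 4)):
                    special.append(_visit_fix(area, config.buffer_radius_m, rng))
            n_alt = rng.poisson(rate_alt)
            n_fast = rng.poisson(rate_fast)
            n_miss = rng.poisson(rate_miss)
            if farm_areas:
                for _ in range(n_alt):
                    a = farm_areas[rng.integers(len(farm_areas))]
                    x, y, _, s = _visit_fix(a, config.buffer_radius_m, rng)
                    special.append((x, y, rng.uniform(30.0, 300.0), s))
                for _ in range(n_fast):
                    a = farm_areas[rng.integers(len(farm_areas))]
                    x, y, agl, _ = _visit_fix(a, config.buffer_radius_m, rng)
                    special.append((x, y, agl, rng.uniform(2.0, 10.0)))
                for _ in range(n_miss):
                    fix = _near_miss_fix(farm_areas, tree, rng)
                    if fix is not None:
                        special.append(fix)

            k = min(len(special), n_slots)
            special_slots = sorted(rng.choice(n_slots, size=k, replace=False)) if k else []
            special_iter = iter(range(k))
            special_set = set(special_slots)
            si = 0
            for i, ts in enumerate(slots):
                if i in special_set and si < k:
                    x, y, agl, speed = special[si]
                    si += 1
                else:
                    ang = rng.uniform(0, 2 * np.pi)
                    r = abs(rng.normal(0.0, config.movement_radius_m / 2.5))
                    x = cx + r * np.cos(ang)
                    y = cy + r * np.sin(ang)
                    xmin, ymin, xmax, ymax = config.extent
                    x = float(np.clip(x, xmin, xmax))
                    y = float(np.clip(y, ymin, ymax))
                    agl = rng.uniform(50.0, 400.0)
                    speed = rng.uniform(6.0, 15.0)
                alt = float(dem.elevation_at(x, y)) + agl
                records.append((bird_id, ts.isoformat(), x, y, alt, speed))

    return pd.DataFrame(
        records, columns=["bird_id", "timestamp", "x", "y", "altitude_m", "speed_ms"]
    )


def _visit_fix(area: FarmArea, radius: float, rng) -> tuple[float, float, float, float]:
    """A qualifying fix near a member farm point, safely inside the
    polygon (offset <= radius - 10 m keeps it within the 64-gon disk)."""
    px, py = area.member_points[rng.integers(len(area.member_points))]
    r = float(np.clip(abs(rng.normal(88.0, 41.0)), 0.0, radius - 10.0))
    ang = rng.uniform(0, 2 * np.pi)
    return (
        px + r * np.cos(ang),
        py + r * np.sin(ang),
        float(rng.uniform(2.0, 20.0)),
        float(rng.uniform(0.0, 1.8)),
    )


def _near_miss_fix(farm_areas, tree, rng):
    """A low/slow fix just outside every farm polygon, or None if a clear
    spot is not found quickly."""
    for _ in range(10):
        area = farm_areas[rng.integers(len(farm_areas))]
        boundary = area.polygon.exterior
        pt = boundary.interpolate(rng.uniform(0.0, boundary.length))
        c = area.polygon.centroid
        vx, vy = pt.x - c.x, pt.y - c.y
        norm = math.hypot(vx, vy) or 1.0
        push = rng.uniform(2.0, 50.0)
        x, y = pt.x + vx / norm * push, pt.y + vy / norm * push
        qi = tree.query(Point(x, y), predicate="covered_by")
        if len(qi) == 0:
            return x, y, float(rng.uniform(2.0, 20.0)), float(rng.uniform(0.0, 1.5))
    return None


def simulate_dataset(config: SimConfig) -> SimulatedDataset:
    """Full generative pipeline: landscape -> farm areas -> disposal ->
    roster -> programmed visit days -> rendered GPS tracks."""
    rng = np.random.default_rng(config.seed + 1)
    farms_df, landscape, dem = simulate_landscape(config)
    semesters = config.semesters
    sem_labels = [s.label for s in semesters]

    farm_objects = [
        Farm(
            farm_id=r["farm_id"],
            x=r["x"],
            y=r["y"],
            herd={s: int(r[f"herd_{s}"]) for s in sem_labels},
        )
        for r in farms_df.to_dict("records")
    ]
    # some farms go inactive in the final semesters
    n_inactive = int(round(config.inactive_farm_fraction * len(farm_objects)))
    inactive_ids = set(
        farms_df["farm_id"].iloc[
            rng.choice(len(farm_objects), size=n_inactive, replace=False)
        ]
        if n_inactive
        else []
    )
    for f in farm_objects:
        if f.farm_id in inactive_ids:
            f.active = {s: i < len(sem_labels) - 2 for i, s in enumerate(sem_labels)}

    # true disposal behaviour and the interviewed subset
    pred = disposal_predictor_table(farms_df, landscape, sem_labels[0])
    answers, known = simulate_disposal(
        pred,
        config.disposal_true_coefficients,
        seed=config.seed + 2,
        known_fraction=config.known_disposal_fraction,
    )
    farms_df = farms_df.copy()
    farms_df["disposal_answer"] = [
        str(int(a)) if k else "" for a, k in zip(answers, known)
    ]
    for f, a, k in zip(farm_objects, answers, known):
        f.disposal_answer = int(a) if k else None

    farm_areas = build_farm_areas(farm_objects, config.buffer_radius_m)
    # ground-truth area-level carcass behaviour: any member abandoning
    truth_by_farm = dict(zip(farms_df["farm_id"], answers))
    area_carcass = {
        a.area_id: float(max(truth_by_farm[m] for m in a.members)) for a in farm_areas
    }

    # bird roster
    first_year = semesters[0].year
    birds = []
    n_terr = int(round(config.fraction_territorial * config.n_birds))
    xmin, ymin, xmax, ymax = config.extent
    for i in range(config.n_birds):
        territorial = i < n_terr
        nest = (
            (rng.uniform(xmin + 2000, xmax - 2000), rng.uniform(ymin + 2000, ymax - 2000))
            if territorial
            else (np.nan, np.nan)
        )
        birds.append(
            {
                "bird_id": f"B{i + 1:03d}",
                "sex": "M" if i % 2 == 0 else "F",
                "birth_year": int(first_year - rng.integers(0, 15)),
                "territorial": territorial,
                "nest_x": nest[0],
                "nest_y": nest[1],
                "success": {s.label: int(rng.random() < 0.5) for s in semesters},
            }
        )
    birds_df = pd.DataFrame(birds)

    # tracked days and activity centres per bird-semester
    tracked_days: dict[str, list[dt.date]] = {b["bird_id"]: [] for b in birds}
    centers: dict[tuple[str, str], tuple[float, float]] = {}
    n_days_by = {}
    for b in birds:
        for sem in semesters:
            if b["territorial"]:
                center = (b["nest_x"], b["nest_y"])
            else:
                center = (
                    rng.uniform(xmin + 2000, xmax - 2000),
                    rng.uniform(ymin + 2000, ymax - 2000),
                )
            centers[(b["bird_id"], sem.label)] = center
            all_days = [sem.start + dt.timedelta(days=i) for i in range(sem.n_days)]
            if config.tracked_day_fraction >= 1.0:
                days = all_days
            else:
                # keep every month above the eligibility floor by default
                per_month = max(16, int(round(30 * config.tracked_day_fraction)))
                days = []
                for yy, mm in sem.months:
                    month_days = [d for d in all_days if (d.year, d.month) == (yy, mm)]
                    take = min(per_month, len(month_days))
                    idx = rng.choice(len(month_days), size=take, replace=False)
                    days.extend(month_days[i] for i in idx)
                days = sorted(days)
            if rng.random() < config.dropout_bird_fraction:
                # degrade one month to 14 data days -> ineligible semester
                yy, mm = sem.months[rng.integers(0, 6)]
                month_days = sorted(d for d in days if (d.year, d.month) == (yy, mm))
                days = sorted(set(days) - set(month_days[14:]))
            tracked_days[b["bird_id"]].extend(days)
            n_days_by[(b["bird_id"], sem.label)] = len(days)

    # generative visit design: candidate areas within movement radius
    rows = []
    for b in birds:
        for sem in semesters:
            cx, cy = centers[(b["bird_id"], sem.label)]
            nd = n_days_by[(b["bird_id"], sem.label)]
            if nd == 0:
                continue
            for a in farm_areas:
                d = math.hypot(a.centroid[0] - cx, a.centroid[1] - cy)
                if d > config.movement_radius_m:
                    continue
                if not a.is_active(sem.label, {f.farm_id: f for f in farm_objects}):
                    continue
                rows.append(
                    {
                        "bird_id": b["bird_id"],
                        "area_id": a.area_id,
                        "semester": sem.label,
                        "denominator": nd,
                        "goat_sheep_raw": a.herd.get(sem.label, 0),
                        "carcass": area_carcass[a.area_id],
                        "dist_road_raw": min(
                            Point(a.centroid).distance(r) for r in landscape.roads
                        ),
                        "dist_hpfp_raw": min(
                            Point(a.centroid).distance(h) for h in landscape.hpfp
                        ),
                        "breeding": sem.breeding,
                    }
                )
    design = pd.DataFrame(rows)
    truth = GroundTruth(
        true_visit_days=set(),
        true_disposal=pd.Series(answers.to_numpy(), index=farms_df["farm_id"]),
        known_mask=pd.Series(known.to_numpy(), index=farms_df["farm_id"]),
        realized_random_effects={},
        true_coefficients={
            "visit": dict(config.visit_true_coefficients),
            "disposal": dict(config.disposal_true_coefficients),
        },
        design=design,
    )
    if len(design):
        for raw, col in [
            ("goat_sheep_raw", "goat_sheep"),
            ("dist_road_raw", "dist_road"),
            ("dist_hpfp_raw", "dist_hpfp"),
        ]:
            v = design[raw].to_numpy(float)
            sd = v.std()
            design[col] = (v - v.mean()) / sd if sd > 0 else 0.0
        v = design["carcass"].to_numpy(float)
        sd = v.std()
        design["carcass"] = (v - v.mean()) / sd if sd > 0 else 0.0
        sds = dict(zip(("area_id", "semester", "bird_id"), config.random_effect_sds))
        numerators, realized = simulate_visit_counts(
            design,
            config.visit_true_coefficients,
            sds,
            seed=config.seed + 3,
        )
        design["numerator"] = numerators
        truth.realized_random_effects = realized

        day_lookup = {
            b: {
                sem.label: sorted(d for d in tracked_days[b] if sem.start <= d <= sem.end)
                for sem in semesters
            }
            for b in tracked_days
        }
        for r in design.itertuples():
            if r.numerator == 0:
                continue
            days = day_lookup[r.bird_id][r.semester]
            chosen = rng.choice(len(days), size=int(r.numerator), replace=False)
            for ci in chosen:
                truth.true_visit_days.add((r.bird_id, r.area_id, days[ci].isoformat()))

    visit_days_typed = {
        (b, a, dt.date.fromisoformat(d)) for b, a, d in truth.true_visit_days
    }
    fixes = render_tracks(
        visit_days_typed,
        {b: sorted(d) for b, d in tracked_days.items()},
        centers,
        farm_areas,
        dem,
        config,
        seed=config.seed + 4,
    )

    return SimulatedDataset(
        config=config,
        farms=farms_df,
        farm_objects=farm_objects,
        farm_areas=farm_areas,
        landscape=landscape,
        dem=dem,
        birds=birds_df,
        fixes=fixes,
        truth=truth,
    )
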