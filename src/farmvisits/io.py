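"""Readers and writers for the pipeline's plain-text interchange formats.

farms.csv      farm_id, x, y, herd_<semester> columns, disposal_answer
fixes.csv      bird_id, ISO-8601 timestamp, x, y, altitude_m, speed_ms
birds.csv      bird_id, sex, birth_year, territorial, nest_x, nest_y
landscape.geojson   features typed by a "kind" property
dem.asc        ESRI ASCII grid
truth.json     ground-truth bookkeeping from the generator
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
from shapely.geometry import mapping, shape

from .geometry import Farm, FarmArea, Landscape

__all__ = [
    "read_farms",
    "write_farms",
    "read_fixes",
    "write_fixes",
    "read_landscape",
    "write_landscape",
    "write_farm_areas",
    "write_truth",
    "read_truth",
]

LANDSCAPE_KINDS = ("road", "urban", "dump", "feeding_station")


def read_farms(path: str | Path) -> list[Farm]:
    df = pd.read_csv(path, dtype={"farm_id": str, "disposal_answer": "string"})
    herd_cols = [c for c in df.columns if c.startswith("herd_")]
    farms = []
    for r in df.to_dict("records"):
        raw = r.get("disposal_answer")
        answer = None if raw is None or pd.isna(raw) or str(raw) == "" else int(float(raw))
        farms.append(
            Farm(
                farm_id=r["farm_id"],
                x=float(r["x"]),
                y=float(r["y"]),
                herd={c[len("herd_"):]: int(r[c]) for c in herd_cols},
                disposal_answer=answer,
            )
        )
    return farms


def write_farms(farms_df: pd.DataFrame, path: str | Path) -> None:
    farms_df.to_csv(path, index=False)


def read_fixes(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"bird_id": str})
    df["timestamp"] = pd.to_datetime(df["timestamp"], utc=True)
    return df.sort_values(["bird_id", "timestamp"], kind="stable").reset_index(drop=True)


def write_fixes(fixes: pd.DataFrame, path: str | Path) -> None:
    fixes.to_csv(path, index=False)


def write_landscape(landscape: Landscape, path: str | Path) -> None:
    features = []
    for kind, geoms in (
        ("road", landscape.roads),
        ("urban", landscape.urban),
        ("dump", landscape.dump),
        ("feeding_station", landscape.feeding_stations),
    ):
        for g in geoms:
            features.append(
                {"type": "Feature", "properties": {"kind": kind}, "geometry": mapping(g)}
            )
    Path(path).write_text(
        json.dumps({"type": "FeatureCollection", "features": features})
    )


def read_landscape(path: str | Path) -> Landscape:
    data = json.loads(Path(path).read_text())
    buckets: dict[str, list] = {k: [] for k in LANDSCAPE_KINDS}
    for feat in data["features"]:
        kind = feat.get("properties", {}).get("kind")
        if kind not in buckets:
            raise ValueError(f"unknown landscape feature kind: {kind!r}")
        buckets[kind].append(shape(feat["geometry"]))
    return Landscape(
        roads=buckets["road"],
        urban=buckets["urban"],
        dump=buckets["dump"],
        feeding_stations=buckets["feeding_station"],
    )


def write_farm_areas(areas: list[FarmArea], path: str | Path) -> None:
    features = []
    for a in areas:
        features.append(
            {
                "type": "Feature",
                "properties": {
                    "area_id": a.area_id,
                    "members": list(a.members),
                    "herd": a.herd,
                    "carcass": a.carcass,
                },
                "geometry": mapping(a.polygon),
            }
        )
    Path(path).write_text(
        json.dumps({"type": "FeatureCollection", "features": features})
    )


def write_truth(truth, path: str | Path) -> None:
    payload = {
        "true_visit_days": sorted(list(t) for t in truth.true_visit_days),
        "true_disposal": {k: int(v) for k, v in truth.true_disposal.items()},
        "known_mask": {k: bool(v) for k, v in truth.known_mask.items()},
        "realized_random_effects": {
            f: {str(k): float(v) for k, v in levels.items()}
            for f, levels in truth.realized_random_effects.items()
        },
        "true_coefficients": truth.true_coefficients,
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_truth(path: str | Path) -> dict:
    data = json.loads(Path(path).read_text())
    data["true_visit_days"] = {tuple(t) for t in data["true_visit_days"]}
    return data
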