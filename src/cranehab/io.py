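"""Readers, writers and the end-to-end report bundle.

File contracts
--------------
Flock observations travel as CSV with header
``flock_id,survey_id,date,species,x,y,count`` (ISO dates; x, y planar
meters). Habitat maps and roost sites are GeoJSON FeatureCollections whose
coordinates are planar meters — a declared deviation from RFC 7946's nominal
WGS84, recorded in the file-level property ``crs_note``. The habitat class
sits in each feature's property ``class``.

Malformed rows are rejected with their line numbers; nothing is silently
dropped.
"""

from __future__ import annotations

import csv
import datetime
import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import Point, mapping, shape

from . import __version__
from .locoh import DEFAULT_LEVELS, DEFAULT_RADIUS_M, IsoplethSet, ud_summary
from .roost import roost_distances, species_comparison, summarize_distances
from .selection import electivity_table, seasonal_electivity
from .survey import (
    AvailabilitySet,
    FlockObservation,
    HabitatMap,
    InputError,
    RoostSite,
    assign_flocks,
    availability_percentages,
)

FLOCK_HEADER = ["flock_id", "survey_id", "date", "species", "x", "y", "count"]

CRS_NOTE = (
    "coordinates are planar meters (projected, e.g. local UTM zone), "
    "NOT WGS84 lon/lat as RFC 7946 nominally requires"
)

log = logging.getLogger("cranehab")


def _looks_geographic(xs: Sequence[float], ys: Sequence[float]) -> bool:
    xs = np.asarray(xs, float)
    ys = np.asarray(ys, float)
    return len(xs) > 0 and bool(
        (np.abs(xs) <= 180).all() and (np.abs(ys) <= 90).all()
    )


def read_flocks(path: str | Path) -> list[FlockObservation]:
    """Read and validate a flock-observation CSV.

    Every malformed row is reported with its line number; any failure is a
    hard error listing all offenders.
    """
    path = Path(path)
    flocks: list[FlockObservation] = []
    errors: list[str] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        missing = [c for c in FLOCK_HEADER if c not in (reader.fieldnames or [])]
        if missing:
            raise InputError(f"{path}: missing column(s) {missing}")
        for lineno, row in enumerate(reader, start=2):
            try:
                flocks.append(
                    FlockObservation(
                        flock_id=row["flock_id"],
                        survey_id=int(row["survey_id"]),
                        date=datetime.date.fromisoformat(row["date"]),
                        species=row["species"],
                        x=float(row["x"]),
                        y=float(row["y"]),
                        count=int(row["count"]),
                    )
                )
            except (InputError, ValueError) as exc:
                errors.append(f"line {lineno}: {exc}")
    if errors:
        raise InputError(f"{path}: {len(errors)} bad row(s):\n" + "\n".join(errors))
    if flocks and _looks_geographic([f.x for f in flocks], [f.y for f in flocks]):
        raise InputError(
            f"{path}: coordinates look geographic (lon/lat); project to planar meters first"
        )
    return flocks


def write_flocks(flocks: Iterable[FlockObservation], path: str | Path) -> None:
    path = Path(path)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(FLOCK_HEADER)
        for f in flocks:
            writer.writerow(
                [f.flock_id, f.survey_id, f.date.isoformat(), f.species,
                 repr(f.x), repr(f.y), f.count]
            )


def write_habitat_map(habitat_map: HabitatMap, path: str | Path) -> None:
    features = [
        {"type": "Feature", "geometry": mapping(poly), "properties": {"class": cls}}
        for poly, cls in habitat_map.polygons
    ]
    _write_feature_collection(features, path)


def read_habitat_map(path: str | Path) -> HabitatMap:
    fc = json.loads(Path(path).read_text(encoding="utf-8"))
    polygons = []
    for i, feat in enumerate(fc.get("features", [])):
        geom = shape(feat["geometry"])
        cls = feat.get("properties", {}).get("class")
        if cls is None:
            raise InputError(f"{path}: feature {i} lacks property 'class'")
        polygons.append((geom, cls))
    return HabitatMap(polygons)


def write_roost(roost: RoostSite, path: str | Path) -> None:
    features = [
        {
            "type": "Feature",
            "geometry": mapping(Point(roost.x, roost.y)),
            "properties": {"label": roost.label},
        }
    ]
    _write_feature_collection(features, path)


def read_roost(path: str | Path) -> RoostSite:
    fc = json.loads(Path(path).read_text(encoding="utf-8"))
    feats = fc.get("features", [])
    if len(feats) != 1:
        raise InputError(f"{path}: expected exactly 1 roost feature, got {len(feats)}")
    geom = shape(feats[0]["geometry"])
    return RoostSite(geom.x, geom.y, feats[0].get("properties", {}).get("label", "roost"))


def write_isopleths(iso: IsoplethSet, path: str | Path) -> None:
    """One Feature per isopleth level with area (ha) and achieved coverage."""
    features = []
    for lv in iso.levels:
        features.append(
            {
                "type": "Feature",
                "geometry": mapping(iso.regions[lv]),
                "properties": {
                    "level": lv,
                    "area_ha": round(iso.area_ha[lv], 2),
                    "coverage": round(iso.coverage[lv], 4),
                },
            }
        )
    _write_feature_collection(features, path)


def _write_feature_collection(features: list[dict], path: str | Path) -> None:
    fc = {"type": "FeatureCollection", "crs_note": CRS_NOTE, "features": features}
    Path(path).write_text(json.dumps(fc, indent=1, sort_keys=True), encoding="utf-8")


@dataclass
class RunConfig:
    """Everything a full report run needs, in one validated place."""

    flocks_path: str | Path
    habitat_path: str | Path
    roost_path: str | Path
    out_dir: str | Path
    available_classes: tuple[str, ...] = ("farmland", "marshland", "grassland")
    radius_m: float = DEFAULT_RADIUS_M
    levels: tuple[float, ...] = DEFAULT_LEVELS
    n_perm: int = 10_000
    seed: int = 0
    precision: dict[str, int] = field(
        default_factory=lambda: {"pct": 1, "s": 2, "area_ha": 2, "km": 2}
    )

    def __post_init__(self) -> None:
        if self.radius_m <= 0:
            raise InputError("radius_m must be > 0")
        for lv in self.levels:
            if not (0.0 < lv <= 1.0):
                raise InputError(f"isopleth level {lv} outside (0, 1]")


def run_report(config: RunConfig) -> dict[str, Path]:
    """End-to-end pipeline: read inputs, run every analysis, write the bundle.

    The bundle mirrors the field-study report shapes: a per-species selection
    table (counts, use %, availability %, pooled and per-survey electivity),
    a per-species isopleth-area table, monthly electivity in long format,
    isopleth GeoJSONs, a roost-distance JSON summary, and a log capturing
    config, seed and versions. Deterministic given the seed: the CLI layer
    adds no computation of its own.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logfile = out / "run.log"
    handler = logging.FileHandler(logfile, mode="w", encoding="utf-8")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    paths: dict[str, Path] = {"log": logfile}
    try:
        log.info(
            "cranehab %s | python %s | numpy %s | seed=%d radius_m=%g levels=%s n_perm=%d",
            __version__, platform.python_version(), np.__version__,
            config.seed, config.radius_m, list(config.levels), config.n_perm,
        )
        stage = "read inputs"
        flocks = read_flocks(config.flocks_path)
        habitat_map = read_habitat_map(config.habitat_path)
        roost = read_roost(config.roost_path)
        log.info("read %d flocks, %d polygons", len(flocks), len(habitat_map.polygons))

        stage = "habitat assignment"
        flocks = assign_flocks(flocks, habitat_map)
        avail = AvailabilitySet.from_map(habitat_map, config.available_classes)
        avail_pct = availability_percentages(habitat_map, avail)
        log.info("availability %%: %s (total %.1f ha)", avail_pct, avail.total_ha)

        p = config.precision
        species_list = sorted({f.species for f in flocks})
        stage = "selection tables"
        for sp in species_list:
            table, n_excluded = electivity_table(
                [f for f in flocks if f.species == sp], avail
            )
            table = table.round(
                {"use_pct": p["pct"], "avail_pct": p["pct"], "s_pooled": p["s"],
                 "s_mean": p["s"], "s_sd": p["s"]}
            )
            fp = out / f"selection_{sp}.csv"
            table.to_csv(fp)
            paths[f"selection_{sp}"] = fp
            log.info("%s: %d flocks excluded (non-available habitat)", sp, n_excluded)

        stage = "monthly electivity"
        monthly = pd.concat(
            [
                seasonal_electivity([f for f in flocks if f.species == sp], avail)
                .assign(species=sp)
                for sp in species_list
            ],
            ignore_index=True,
        ).round({"use_pct": p["pct"], "s": p["s"]})
        fp = out / "monthly_electivity.csv"
        monthly.to_csv(fp, index=False)
        paths["monthly_electivity"] = fp

        stage = "utilization distribution"
        pts = {
            sp: np.array([[f.x, f.y] for f in flocks if f.species == sp])
            for sp in species_list
        }
        ud, iso_sets = ud_summary(pts, r=config.radius_m, levels=config.levels)
        fp = out / "ud_areas.csv"
        ud.to_csv(fp)
        paths["ud_areas"] = fp
        for sp, iso in iso_sets.items():
            gp = out / f"isopleths_{sp}.geojson"
            write_isopleths(iso, gp)
            paths[f"isopleths_{sp}"] = gp

        stage = "roost distances"
        dist = roost_distances(flocks, roost)
        fp = out / "roost_distances.csv"
        dist.round({"distance_km": 4}).to_csv(fp, index=False)
        paths["roost_distances"] = fp
        summary = summarize_distances(dist).round(p["km"])
        result: dict[str, object] = {
            "per_species": summary.to_dict(orient="index"),
            "availability_pct": avail_pct,
            "total_available_ha": round(avail.total_ha, p["area_ha"]),
        }
        if len(species_list) == 2:
            cmp = species_comparison(dist, n_perm=config.n_perm, seed=config.seed)
            result["comparison"] = cmp
            log.info(
                "species comparison: delta=%.3f km, permutation p=%.4g, F=%.2f",
                cmp["delta_km"], cmp["p_permutation"], cmp["f_species"],
            )
        fp = out / "distance_summary.json"
        fp.write_text(json.dumps(result, indent=1, sort_keys=True), encoding="utf-8")
        paths["distance_summary"] = fp
        log.info("report complete: %d artifacts", len(paths))
        return paths
    except Exception as exc:
        log.error("stage %r failed: %s", stage, exc)
        raise RuntimeError(f"report stage {stage!r} failed: {exc}") from exc
    finally:
        log.removeHandler(handler)
        handler.close()
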