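"""Fixed-radius local convex hull (r-LoCoH) utilization distributions.

For every observation point the local hull is the convex hull of all points
within radius ``r`` of it (the root included). Hulls are sorted smallest-area
first — the LoCoH density heuristic: small local hulls mean locally dense
use — and unioned cumulatively; the p% isopleth is the first running union
whose closed region contains at least p% of all points. Nested 50/70/90%
isopleths then delimit the core, ordinary and overall distribution ranges.

Degenerate local hulls (fewer than three distinct, non-collinear members) are
points or segments with zero area; they still count toward coverage, so
duplicate coordinates are legitimate inputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import shapely
from scipy.spatial import cKDTree
from shapely.geometry import MultiPoint
from shapely.geometry.base import BaseGeometry

from .survey import InputError

#: Default hull radius, meters; matches the flock-discreteness distance.
DEFAULT_RADIUS_M = 500.0

DEFAULT_LEVELS = (0.50, 0.70, 0.90)


@dataclass
class LocalHull:
    """Convex hull of all points within ``r`` of one root point."""

    root_id: int
    member_ids: np.ndarray
    polygon: BaseGeometry  # Point / LineString for degenerate member sets
    hull_area: float  # m^2
    n_enclosed: int  # input points (members or not) inside the closed hull


@dataclass
class IsoplethSet:
    """Nested utilization-distribution isopleths.

    ``regions[p]`` is the (possibly multi-part) polygon of the p-level
    isopleth, ``area_ha[p]`` its area in hectares, ``coverage[p]`` the
    achieved fraction of points inside it (always >= p).
    """

    regions: dict[float, BaseGeometry]
    area_ha: dict[float, float]
    coverage: dict[float, float]

    @property
    def levels(self) -> tuple[float, ...]:
        return tuple(sorted(self.regions))


def build_local_hulls(
    points: Sequence[tuple[float, float]] | np.ndarray,
    r: float = DEFAULT_RADIUS_M,
) -> list[LocalHull]:
    """One local hull per point: membership by Euclidean distance <= ``r``."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) == 0:
        raise InputError("points must be a non-empty (n, 2) array")
    if not np.isfinite(pts).all():
        raise InputError("non-finite coordinates")
    if r <= 0:
        raise InputError("radius r must be > 0")
    tree = cKDTree(pts)
    members_per_root = tree.query_ball_point(pts, r=r)
    geoms = shapely.points(pts[:, 0], pts[:, 1])
    hulls = []
    for root, members in enumerate(members_per_root):
        members = np.sort(np.asarray(members, dtype=int))
        hull = MultiPoint(pts[members]).convex_hull
        n_enclosed = int(shapely.covers(hull, geoms).sum())
        hulls.append(LocalHull(root, members, hull, hull.area, n_enclosed))
    return hulls


def sort_hulls(hulls: Sequence[LocalHull]) -> list[LocalHull]:
    """LoCoH ordering: ascending area, ties by descending enclosed-point
    count, remaining ties by ascending root id (deterministic)."""
    return sorted(hulls, key=lambda h: (h.hull_area, -h.n_enclosed, h.root_id))


def build_isopleths(
    sorted_hulls: Sequence[LocalHull],
    points: Sequence[tuple[float, float]] | np.ndarray,
    levels: Sequence[float] = DEFAULT_LEVELS,
) -> IsoplethSet:
    """Cumulative-union isopleths from hulls already in LoCoH order.

    Walks the sorted hulls maintaining a running union; after every union
    step the fraction of all points inside the closed union is recomputed
    (summing per-hull counts would double-count shared points). The isopleth
    for level p is the first running union reaching coverage >= p.
    """
    for lv in levels:
        if not (0.0 < lv <= 1.0):
            raise InputError(f"isopleth level must be in (0, 1], got {lv}")
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) == 0:
        raise InputError("points must be a non-empty (n, 2) array")
    geoms = shapely.points(pts[:, 0], pts[:, 1])
    n = len(pts)
    pending = sorted(set(levels))
    regions: dict[float, BaseGeometry] = {}
    area_ha: dict[float, float] = {}
    coverage: dict[float, float] = {}
    union: BaseGeometry | None = None
    covered = np.zeros(n, dtype=bool)
    for hull in sorted_hulls:
        union = hull.polygon if union is None else shapely.union_all([union, hull.polygon])
        covered |= shapely.covers(hull.polygon, geoms)
        frac = covered.sum() / n
        while pending and frac >= pending[0]:
            lv = pending.pop(0)
            regions[lv] = union
            area_ha[lv] = union.area / 1e4
            coverage[lv] = float(frac)
        if not pending:
            break
    if pending:
        # cannot happen when every point roots a hull, but guard partial input
        raise InputError(
            f"hull walk exhausted at coverage {covered.sum() / n:.3f} "
            f"before reaching levels {pending}"
        )
    return IsoplethSet(regions, area_ha, coverage)


def isopleths(
    points: Sequence[tuple[float, float]] | np.ndarray,
    r: float = DEFAULT_RADIUS_M,
    levels: Sequence[float] = DEFAULT_LEVELS,
) -> IsoplethSet:
    """Full r-LoCoH pipeline: hulls, sort, cumulative isopleths."""
    pts = np.asarray(points, dtype=float)
    if len(pts) and len(np.unique(pts, axis=0)) < 3:
        warnings.warn("fewer than 3 distinct points: isopleths have zero area")
    hulls = sort_hulls(build_local_hulls(pts, r))
    return build_isopleths(hulls, pts, levels)


def ud_summary(
    points_by_species: Mapping[str, np.ndarray],
    r: float = DEFAULT_RADIUS_M,
    levels: Sequence[float] = DEFAULT_LEVELS,
) -> tuple["pd.DataFrame", dict[str, IsoplethSet]]:
    """Per-species isopleth areas (hectares, 2 decimals) plus the polygons."""
    import pandas as pd

    sets = {}
    rows = {}
    for species, pts in points_by_species.items():
        iso = isopleths(pts, r=r, levels=levels)
        sets[species] = iso
        rows[species] = {
            f"isopleth_{int(round(lv * 100))}_ha": round(iso.area_ha[lv], 2)
            for lv in sorted(levels, reverse=True)
        }
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "species"
    return df, sets
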