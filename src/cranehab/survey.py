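"""Core survey domain: flock observations, habitat maps, availability, flock clustering.

All geometry is planar and in meters. Field coordinates recorded in
longitude/latitude must be projected to a metric system (e.g. the local UTM
zone) before they enter this package; distances are Euclidean and areas are
reported in hectares (1 ha = 10,000 m^2), so geographic coordinates would be
silently wrong. Inputs whose coordinates look geographic (|x| <= 180 and
|y| <= 90 for every point) are rejected on read, see :mod:`cranehab.io`.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from datetime import date as _date
from typing import Iterable, Sequence

import numpy as np
import shapely
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree
from shapely.geometry import Point, Polygon

HABITAT_CLASSES = (
    "farmland",
    "marshland",
    "grassland",
    "woodland",
    "water",
    "residential",
)

#: Habitats counted as available foraging habitat for wintering cranes.
AVAILABLE_CLASSES = ("farmland", "marshland", "grassland")

SPECIES_CODES = ("BNC", "CC")  # black-necked crane, common crane

#: Flocks further apart than this are discrete sample units (meters).
FLOCK_DISCRETENESS_M = 500.0


class InputError(ValueError):
    """Invalid user-supplied data (bad coordinates, counts, classes...)."""


@dataclass(frozen=True)
class FlockObservation:
    """One discrete crane flock recorded as a single GPS point.

    The flock — not the individual bird — is the sample unit: ``count`` is
    carried through for reporting but no statistic in the pipeline weights
    by it.
    """

    flock_id: str
    survey_id: int
    date: _date
    species: str
    x: float
    y: float
    count: int
    habitat: str = "unassigned"

    def __post_init__(self) -> None:
        if self.species not in SPECIES_CODES:
            raise InputError(
                f"unknown species code {self.species!r}; expected one of {SPECIES_CODES}"
            )
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise InputError(f"flock {self.flock_id!r}: non-finite coordinates")
        if self.count < 1:
            raise InputError(f"flock {self.flock_id!r}: count must be >= 1, got {self.count}")
        if self.habitat not in HABITAT_CLASSES + ("unassigned", "none"):
            raise InputError(f"flock {self.flock_id!r}: unknown habitat {self.habitat!r}")

    @property
    def month(self) -> int:
        return self.date.month


@dataclass(frozen=True)
class RoostSite:
    """The communal nightly roosting site (planar meters)."""

    x: float
    y: float
    label: str = "roost"

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise InputError("roost site has non-finite coordinates")


class HabitatMap:
    """Classified, non-overlapping habitat polygons in planar meters.

    Polygons keep their insertion order; a point on a shared boundary is
    assigned to the earliest polygon containing it, which makes habitat
    assignment deterministic and order-stable.

    Parameters
    ----------
    polygons :
        ``(polygon, habitat_class)`` pairs. Each polygon must be simple
        (valid, non-self-intersecting).
    overlap_tol_m2 :
        Maximum tolerated pairwise interior overlap, in m^2.
    """

    def __init__(
        self,
        polygons: Sequence[tuple[Polygon, str]],
        overlap_tol_m2: float = 1.0,
    ) -> None:
        polys: list[Polygon] = []
        classes: list[str] = []
        for i, (poly, cls) in enumerate(polygons):
            if cls not in HABITAT_CLASSES:
                raise InputError(f"polygon {i}: unknown habitat class {cls!r}")
            if not isinstance(poly, Polygon) or poly.is_empty:
                raise InputError(f"polygon {i}: expected a non-empty polygon")
            if not poly.is_valid:
                raise InputError(f"polygon {i}: not a simple polygon")
            polys.append(poly)
            classes.append(cls)
        for i in range(len(polys)):
            for j in range(i + 1, len(polys)):
                inter = polys[i].intersection(polys[j])
                if inter.area > overlap_tol_m2:
                    raise InputError(
                        f"polygons {i} and {j} overlap by {inter.area:.1f} m^2 "
                        f"(> {overlap_tol_m2} m^2 tolerance)"
                    )
        self._polygons = polys
        self._classes = classes

    @property
    def polygons(self) -> list[tuple[Polygon, str]]:
        return list(zip(self._polygons, self._classes))

    @property
    def classes(self) -> tuple[str, ...]:
        """Distinct habitat classes present, in first-appearance order."""
        seen: list[str] = []
        for c in self._classes:
            if c not in seen:
                seen.append(c)
        return tuple(seen)

    def class_area_m2(self, habitat: str) -> float:
        return sum(p.area for p, c in zip(self._polygons, self._classes) if c == habitat)

    def class_area_ha(self, habitat: str) -> float:
        return self.class_area_m2(habitat) / 1e4

    def assign(self, x: float, y: float) -> str:
        """Habitat class of the first (insertion order) polygon whose closed
        region contains ``(x, y)``; ``"none"`` if outside all polygons."""
        if not (math.isfinite(x) and math.isfinite(y)):
            raise InputError("assign: non-finite coordinates")
        pt = Point(x, y)
        for poly, cls in zip(self._polygons, self._classes):
            if poly.covers(pt):
                return cls
        return "none"

    def assign_many(self, xs: np.ndarray, ys: np.ndarray) -> np.ndarray:
        """Vectorised :meth:`assign` for coordinate arrays."""
        xs = np.asarray(xs, dtype=float)
        ys = np.asarray(ys, dtype=float)
        if not (np.isfinite(xs).all() and np.isfinite(ys).all()):
            raise InputError("assign_many: non-finite coordinates")
        pts = shapely.points(xs, ys)
        out = np.full(xs.shape, "none", dtype=object)
        unassigned = np.ones(xs.shape, dtype=bool)
        for poly, cls in zip(self._polygons, self._classes):
            if not unassigned.any():
                break
            hit = unassigned & shapely.covers(poly, pts)
            out[hit] = cls
            unassigned &= ~hit
        return out


def assign_habitat(point: tuple[float, float], habitat_map: HabitatMap) -> str:
    """Habitat class at ``point``; ``"none"`` outside all mapped polygons."""
    return habitat_map.assign(point[0], point[1])


def assign_flocks(
    flocks: Iterable[FlockObservation], habitat_map: HabitatMap
) -> list[FlockObservation]:
    """Return flocks with ``habitat`` filled in from the map."""
    flocks = list(flocks)
    if not flocks:
        return []
    xs = np.array([f.x for f in flocks])
    ys = np.array([f.y for f in flocks])
    classes = habitat_map.assign_many(xs, ys)
    out = []
    for f, cls in zip(flocks, classes):
        out.append(
            FlockObservation(
                f.flock_id, f.survey_id, f.date, f.species, f.x, f.y, f.count, str(cls)
            )
        )
    return out


@dataclass
class AvailabilitySet:
    """Per-class areas of the habitats deemed available foraging habitat.

    Availability percentages (the ``b`` of the electivity index) are a fixed
    landscape property: ``100 * area_ha[class] / total_ha``.
    """

    area_ha: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for cls, a in self.area_ha.items():
            if cls not in HABITAT_CLASSES:
                raise InputError(f"unknown habitat class {cls!r}")
            if a <= 0:
                raise InputError(f"class {cls!r}: area must be > 0 (got {a})")
        if self.total_ha <= 0:
            raise InputError("total available area must be > 0")

    @property
    def classes(self) -> tuple[str, ...]:
        return tuple(self.area_ha)

    @property
    def total_ha(self) -> float:
        return float(sum(self.area_ha.values()))

    @classmethod
    def from_map(
        cls, habitat_map: HabitatMap, classes: Sequence[str] = AVAILABLE_CLASSES
    ) -> "AvailabilitySet":
        areas = {}
        for c in classes:
            a = habitat_map.class_area_ha(c)
            if a <= 0:
                warnings.warn(f"available class {c!r} has zero area in the map; dropped")
                continue
            areas[c] = a
        return cls(areas)

    def percentages(self) -> dict[str, float]:
        total = self.total_ha
        return {c: round(100.0 * a / total, 1) for c, a in self.area_ha.items()}


def availability_percentages(
    habitat_map: HabitatMap | None,
    avail: AvailabilitySet | None = None,
) -> dict[str, float]:
    """Availability percentage per class, rounded to one decimal.

    ``avail`` takes precedence; with only a map the default available classes
    (farmland, marshland, grassland) are measured from it. A requested class
    with no mapped area raises a warning and is dropped.
    """
    if avail is None:
        if habitat_map is None:
            raise InputError("need a habitat map or an availability set")
        avail = AvailabilitySet.from_map(habitat_map)
    elif habitat_map is not None:
        for c in avail.classes:
            if habitat_map.class_area_ha(c) == 0.0:
                warnings.warn(f"class {c!r} in availability set is absent from the map")
    return avail.percentages()


def cluster_flocks(
    points: Sequence[tuple[float, float]] | np.ndarray,
    threshold_m: float = FLOCK_DISCRETENESS_M,
) -> np.ndarray:
    """Partition point records into discrete flocks by single linkage.

    Two records belong to the same flock iff they are connected by a chain of
    pairwise Euclidean distances <= ``threshold_m`` (strictly more than the
    threshold apart means discrete). The returned integer labels are numbered
    by first appearance, so the partition is order-stable and permutation- and
    rigid-motion-invariant as a set partition.
    """
    pts = np.asarray(points, dtype=float)
    if pts.size == 0:
        return np.empty(0, dtype=int)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise InputError("points must be an (n, 2) array")
    if not np.isfinite(pts).all():
        raise InputError("non-finite coordinates")
    if threshold_m <= 0:
        raise InputError("threshold_m must be > 0")
    n = len(pts)
    tree = cKDTree(pts)
    pairs = tree.query_pairs(r=threshold_m, output_type="ndarray")
    if len(pairs):
        row = np.concatenate([pairs[:, 0], pairs[:, 1]])
        col = np.concatenate([pairs[:, 1], pairs[:, 0]])
        graph = csr_matrix((np.ones(len(row)), (row, col)), shape=(n, n))
    else:
        graph = csr_matrix((n, n))
    _, labels = connected_components(graph, directed=False)
    # renumber components by first appearance for determinism
    order: dict[int, int] = {}
    out = np.empty(n, dtype=int)
    for i, lab in enumerate(labels):
        if lab not in order:
            order[lab] = len(order)
        out[i] = order[lab]
    return out
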