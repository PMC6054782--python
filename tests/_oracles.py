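"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive: O(n^2) distance matrices, monotone-
chain hulls, shoelace areas, cross-product containment, one-shot polygon
unions. None of it shares code with the package's computation paths.
"""

from __future__ import annotations

import numpy as np
from shapely.geometry import LineString, Point, Polygon
from shapely.ops import unary_union

EPS = 1e-9


def ray_cast_contains(poly_xy: np.ndarray, x: float, y: float) -> bool:
    """Even-odd ray casting for a simple polygon given as an (n, 2) ring.

    Strictly-interior test; points on the boundary are not guaranteed a
    stable answer (callers avoid them).
    """
    inside = False
    n = len(poly_xy)
    for i in range(n):
        x1, y1 = poly_xy[i]
        x2, y2 = poly_xy[(i + 1) % n]
        if (y1 > y) != (y2 > y):
            xcross = x1 + (y - y1) * (x2 - x1) / (y2 - y1)
            if x < xcross:
                inside = not inside
    return inside


def monotone_chain_hull(pts: np.ndarray) -> np.ndarray:
    """Andrew's monotone chain; returns hull vertices CCW (may be 1 or 2
    points for degenerate inputs)."""
    pts = np.unique(np.asarray(pts, float), axis=0)
    if len(pts) <= 2:
        return pts
    pts = pts[np.lexsort((pts[:, 1], pts[:, 0]))]

    def cross(o, a, b):
        return (a[0] - o[0]) * (b[1] - o[1]) - (a[1] - o[1]) * (b[0] - o[0])

    lower: list[np.ndarray] = []
    for p in pts:
        while len(lower) >= 2 and cross(lower[-2], lower[-1], p) <= 0:
            lower.pop()
        lower.append(p)
    upper: list[np.ndarray] = []
    for p in pts[::-1]:
        while len(upper) >= 2 and cross(upper[-2], upper[-1], p) <= 0:
            upper.pop()
        upper.append(p)
    hull = np.array(lower[:-1] + upper[:-1])
    if len(hull) < 3:  # all collinear
        i = np.argmin(pts[:, 0] + pts[:, 1])
        j = np.argmax(pts[:, 0] + pts[:, 1])
        return np.array([pts[i], pts[j]])
    return hull


def shoelace_area(ring: np.ndarray) -> float:
    if len(ring) < 3:
        return 0.0
    x, y = ring[:, 0], ring[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def hull_contains(hull: np.ndarray, p: np.ndarray) -> bool:
    """Closed containment in a (possibly degenerate) convex hull."""
    if len(hull) == 1:
        return bool(np.allclose(hull[0], p, atol=EPS))
    if len(hull) == 2:
        a, b = hull
        ab = b - a
        t = np.dot(p - a, ab) / max(np.dot(ab, ab), EPS)
        proj = a + np.clip(t, 0.0, 1.0) * ab
        return bool(np.hypot(*(p - proj)) <= EPS)
    n = len(hull)
    sign = 0
    for i in range(n):
        a, b = hull[i], hull[(i + 1) % n]
        cr = (b[0] - a[0]) * (p[1] - a[1]) - (b[1] - a[1]) * (p[0] - a[0])
        if abs(cr) <= EPS * max(1.0, abs(cr)):
            continue
        s = 1 if cr > 0 else -1
        if sign == 0:
            sign = s
        elif s != sign:
            return False
    return True


def _hull_geom(hull: np.ndarray):
    if len(hull) == 1:
        return Point(hull[0])
    if len(hull) == 2:
        return LineString(hull)
    return Polygon(hull)


def brute_force_isopleths(
    pts: np.ndarray, r: float, levels=(0.5, 0.7, 0.9)
) -> dict[float, float]:
    """r-LoCoH isopleth areas (m^2) by explicit enumeration.

    Own hulls, own sort, own containment; the final union is a one-shot
    shapely ``unary_union`` over an explicit hull list (vs the package's
    incremental union walk).
    """
    pts = np.asarray(pts, float)
    n = len(pts)
    d = np.hypot(pts[:, None, 0] - pts[None, :, 0], pts[:, None, 1] - pts[None, :, 1])
    hulls = []
    for root in range(n):
        members = pts[d[root] <= r]
        hv = monotone_chain_hull(members)
        area = shoelace_area(hv)
        enclosed = sum(1 for q in pts if hull_contains(hv, q))
        hulls.append((area, -enclosed, root, hv))
    hulls.sort(key=lambda t: t[:3])
    areas: dict[float, float] = {}
    pending = sorted(levels)
    for k in range(1, n + 1):
        frac = (
            sum(1 for q in pts if any(hull_contains(h[3], q) for h in hulls[:k])) / n
        )
        while pending and frac >= pending[0]:
            lv = pending.pop(0)
            areas[lv] = unary_union([_hull_geom(h[3]) for h in hulls[:k]]).area
        if not pending:
            break
    return areas


def brute_force_flock_components(pts: np.ndarray, threshold: float) -> list[set[int]]:
    """Connected components of the <=threshold proximity graph by BFS."""
    pts = np.asarray(pts, float)
    n = len(pts)
    d = np.hypot(pts[:, None, 0] - pts[None, :, 0], pts[:, None, 1] - pts[None, :, 1])
    seen = set()
    comps = []
    for start in range(n):
        if start in seen:
            continue
        comp = {start}
        frontier = [start]
        while frontier:
            i = frontier.pop()
            for j in range(n):
                if j not in comp and d[i, j] <= threshold:
                    comp.add(j)
                    frontier.append(j)
        seen |= comp
        comps.append(comp)
    return comps
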