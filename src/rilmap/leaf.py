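"""Leaflet-shape morphometrics: lobed-area ratio R, length ratio Q, apex
count NA, and the 1:1 segregation test for leaflet classes.

Definitions (percent scales):

* ``R = 100 * V / A`` where ``V`` is the actual blade area and
  ``A = V + lobed`` adds the lobed (notch) areas, so an unlobed leaf has
  R = 100;
* ``Q = 100 * L1 / L2`` where ``L2`` is the base-to-tip main-vein length
  and ``L1`` the distance from the base to where the chord joining the
  deepest concave-point pair crosses the vein;
* ``NA`` is the number of apexes around the leaf margin.

Lobed areas are measured by chord closure of the annotated concave pairs:
each notch is the pocket between the polygon and its convex hull that
contains an annotated concave vertex.  Filtering pockets by annotation
keeps the convex tip and base from inflating ``A``.
"""

from __future__ import annotations

import numpy as np
from scipy import stats
from shapely.geometry import LineString, MultiPolygon, Point, Polygon

from .simulate import LeafShape

#: minimal apex prominence, as a fraction of the main-vein length
APEX_PROMINENCE = 0.01


def compute_R(V: float, lobed_area: float) -> float:
    """Area ratio ``R = 100 * V / (V + lobed_area)``."""
    if V <= 0:
        raise ValueError("blade area V must be positive")
    if lobed_area < 0:
        raise ValueError("lobed area cannot be negative")
    return 100.0 * V / (V + lobed_area)


def compute_Q(L1: float, L2: float) -> float:
    """Length ratio ``Q = 100 * L1 / L2`` with ``0 < L1 <= L2``."""
    if L1 <= 0:
        raise ValueError("L1 must be positive (degenerate landmark otherwise)")
    if L1 > L2:
        raise ValueError("L1 exceeds L2: inconsistent landmarks")
    return 100.0 * L1 / L2


def measure_from_polygon(shape: LeafShape) -> tuple[float, float, float, float]:
    """Measure ``(V, lobed_area, L1, L2)`` from an annotated leaf polygon.

    ``V`` is the shoelace area.  Each annotated concave vertex selects the
    convex-hull pocket it borders; distinct pockets' areas sum to the
    lobed area.  ``L1`` comes from the chord of the deepest concave pair
    (largest combined pocket area); with no concave pairs ``L1 = L2``.
    Raises if a chord fails to cross the main vein, naming the pair.
    """
    poly = Polygon(shape.vertices)
    if not poly.is_valid or not poly.is_simple:
        raise ValueError("leaf outline is not a simple polygon")
    V = poly.area
    base = Point(shape.vertices[shape.base_index])
    tip = Point(shape.vertices[shape.tip_index])
    L2 = base.distance(tip)

    if not shape.concave_pairs:
        return V, 0.0, L2, L2

    pockets_geom = poly.convex_hull.difference(poly)
    pockets = (
        list(pockets_geom.geoms)
        if isinstance(pockets_geom, MultiPolygon)
        else ([pockets_geom] if pockets_geom.area > 0 else [])
    )

    tol = 1e-9 * max(L2, 1.0)
    used: set[int] = set()
    pair_depth: list[float] = []
    for left, right in shape.concave_pairs:
        depth = 0.0
        for vi in (left, right):
            pt = Point(shape.vertices[vi])
            for k, pk in enumerate(pockets):
                if pk.distance(pt) <= tol:
                    depth += pk.area if k not in used else 0.0
                    used.add(k)
                    break
        pair_depth.append(depth)
    lobed = float(sum(pockets[k].area for k in used))

    deepest = shape.concave_pairs[int(np.argmax(pair_depth))]
    chord = LineString([shape.vertices[deepest[0]], shape.vertices[deepest[1]]])
    vein = LineString([base, tip])
    inter = chord.intersection(vein)
    if inter.is_empty:
        raise ValueError(f"concave-pair chord {deepest} does not cross the main vein")
    if inter.geom_type != "Point":      # collinear overlap: take its midpoint
        inter = inter.centroid
    L1 = base.distance(inter)
    return V, lobed, L1, L2


def count_apexes(shape: LeafShape) -> int:
    """Number of margin apexes.

    An annotated apex set takes precedence.  Otherwise apexes are strict
    circular local maxima of the distance from the outline to the polygon
    centroid, kept only when their prominence over the adjacent minima
    exceeds ``APEX_PROMINENCE`` of the main-vein length, which suppresses
    discretisation ripple.
    """
    if shape.apex_indices:
        return len(shape.apex_indices)
    verts = shape.vertices
    c = Polygon(verts).centroid
    d = np.hypot(verts[:, 0] - c.x, verts[:, 1] - c.y)
    L2 = float(
        np.hypot(*(verts[shape.tip_index] - verts[shape.base_index]))
    )
    n = len(d)
    count = 0
    for i in range(n):
        if not (d[i] > d[(i - 1) % n] and d[i] > d[(i + 1) % n]):
            continue
        # walk to the nearest local minimum on each side
        lo = []
        for step in (-1, 1):
            j = i
            while True:
                nxt = (j + step) % n
                if d[nxt] > d[j] or nxt == i:
                    break
                j = nxt
            lo.append(d[j])
        if d[i] - max(lo) >= APEX_PROMINENCE * L2:
            count += 1
    return count


def segregation_fit(class_counts: tuple[int, int], expected_ratio: tuple[int, int] = (1, 1)) -> tuple[float, float]:
    """Chi-square goodness of fit of two class counts to an expected ratio
    (1 df, no continuity correction)."""
    a, b = class_counts
    total = a + b
    if total <= 0:
        raise ValueError("segregation test needs a positive total count")
    w = expected_ratio[0] + expected_ratio[1]
    expected = (total * expected_ratio[0] / w, total * expected_ratio[1] / w)
    chi2, p = stats.chisquare([a, b], f_exp=expected)
    return float(chi2), float(p)


def classify_leaf(
    NA: float, R: float, lobed_R_below: float = 95.0, indented_NA_above: float = 3.0
) -> str:
    """Leaflet class from phenotype values.

    ``lobed`` when the area ratio R drops below ``lobed_R_below``,
    ``indented`` when the apex count exceeds ``indented_NA_above``,
    ``mixed`` when both hold (such lines are excluded from QTL input),
    else ``ovate``.
    """
    lobed = R < lobed_R_below
    indented = NA > indented_NA_above
    if lobed and indented:
        return "mixed"
    if lobed:
        return "lobed"
    if indented:
        return "indented"
    return "ovate"


def phenotypes_from_shapes(shapes: dict[str, LeafShape]) -> "pd.DataFrame":
    """Measure NA, R, Q and class for a set of per-line leaf shapes."""
    import pandas as pd

    rows = []
    for line_id, shape in shapes.items():
        V, lobed, L1, L2 = measure_from_polygon(shape)
        R = compute_R(V, lobed)
        Q = compute_Q(L1, L2)
        NA = count_apexes(shape)
        rows.append((line_id, NA, R, Q, classify_leaf(NA, R)))
    return pd.DataFrame(rows, columns=["line_id", "NA", "R", "Q", "class"])
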