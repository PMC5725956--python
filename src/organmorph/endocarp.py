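"""Endocarp-specific analysis: roughness, grooves and circle descriptors.

The olive endocarp ("stone") is the most discriminative organ for cultivar
identification; besides the common descriptors taken in positions A and B,
its vertical cross-view (position C, facing the petiole-insertion end)
exposes surface sculpture:

* area convexity ``StArConv`` = area / convex-hull area (1 for smooth,
  lower for grooved stones);
* min/max distance from the area centroid to the contour;
* diameters of the maximum inscribed and minimum bounding circles;
* groove depths, measured per convex-hull *pocket*: for each hull edge the
  depth is the maximum perpendicular distance from that edge to the
  contour points it spans.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import shapely
from scipy.spatial import ConvexHull
from shapely.geometry import Polygon

from .contour import Contour
from .descriptors import basic_size, extreme_arc, mean_curvature, shape_scores

__all__ = [
    "EndocarpParams",
    "EndocarpVertical",
    "EndocarpTraits",
    "area_convexity",
    "centre_distances",
    "inscribed_circle_diameter",
    "bounding_circle_diameter",
    "min_enclosing_circle",
    "groove_depths",
    "endocarp_profile",
]

DEFAULT_DEPTH_FLOOR_FRAC = 0.005  # of DiamMinBdCir; excludes raster noise pockets


@dataclass(frozen=True)
class EndocarpParams:
    arc_fraction: float = 0.05
    ver_sym_from_base: bool = False
    depth_floor_frac: float = DEFAULT_DEPTH_FLOOR_FRAC
    inscribed_resolution_frac: float = 0.002  # of the bbox diagonal


@dataclass(frozen=True)
class EndocarpVertical:
    st_ar_conv: float
    min_cent_cnt: float
    max_cent_cnt: float
    diam_inscr_cir: float
    diam_min_bd_cir: float
    groove_mean_depth: float
    groove_max_depth: float
    groove_count: int
    perim_convexity: float  # hull perimeter / contour perimeter
    centre: tuple


# ---------------------------------------------------------------------------
# the four vertical-position primitives


def area_convexity(contour: Contour) -> float:
    """Area / convex-hull area; 1 for convex outlines, < 1 for grooved ones."""
    hull = ConvexHull(contour.vertices)
    return float(contour.area() / hull.volume)


def centre_distances(contour: Contour) -> tuple[float, float]:
    """(min, max) Euclidean distance from the area centroid to the polyline.

    The minimum is a true point-to-segment distance; the maximum over a
    polygonal boundary is always attained at a vertex.  A centroid lying
    outside the polygon (strongly non-star-shaped outline) only warns.
    """
    c = contour.centroid()
    poly = Polygon(contour.vertices)
    if not poly.contains(shapely.points(c)):
        warnings.warn("centroid lies outside the contour", stacklevel=2)
    dmin = float(poly.exterior.distance(shapely.points(c)))
    dmax = float(np.max(np.hypot(*(contour.vertices - c).T)))
    return dmin, dmax


def inscribed_circle_diameter(contour: Contour,
                              resolution_frac: float = 0.002) -> float:
    """Diameter of the largest circle fully inside the polygon.

    Coarse interior grid of clearance (distance to boundary) values, then
    iterative local grid refinement around the best candidates until the
    step is below ``resolution_frac`` of the bounding-box diagonal.
    """
    v = contour.vertices
    poly = Polygon(v)
    exterior = poly.exterior
    x0, y0, x1, y1 = poly.bounds
    diag = float(np.hypot(x1 - x0, y1 - y0))
    target = resolution_frac * diag / 4.0

    def clearance(pts: np.ndarray) -> np.ndarray:
        geoms = shapely.points(pts)
        inside = shapely.contains(poly, geoms)
        d = shapely.distance(geoms, exterior)
        return np.where(inside, d, -d)

    nx = 64
    gx, gy = np.meshgrid(np.linspace(x0, x1, nx), np.linspace(y0, y1, nx))
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    d = clearance(pts)
    order = np.argsort(d)[::-1]
    # refine a handful of well-separated seeds (the clearance field can be
    # multimodal, e.g. L-shaped outlines)
    seeds, taken = [], []
    min_sep = diag / 8.0
    for i in order:
        if d[i] <= 0:
            break
        p = pts[i]
        if all(np.hypot(*(p - q)) > min_sep for q in taken):
            seeds.append(p)
            taken.append(p)
        if len(seeds) >= 5:
            break
    best = 0.0
    step0 = diag / nx
    for seed in seeds:
        p, step = np.asarray(seed, dtype=float), step0
        val = clearance(p[None, :])[0]
        while step > target:
            off = np.array([[dx, dy] for dx in (-1, 0, 1) for dy in (-1, 0, 1)])
            cand = p + step * off
            dc = clearance(cand)
            j = int(np.argmax(dc))
            if dc[j] > val:
                p, val = cand[j], dc[j]
            else:
                step /= 2.0
        best = max(best, val)
    return float(2.0 * best)


def min_enclosing_circle(points: np.ndarray) -> tuple[np.ndarray, float]:
    """Exact minimum enclosing circle of a point set (Welzl-type incremental).

    Returns (centre, radius).  Deterministic: points are pre-shuffled with a
    fixed seed, which gives the expected-linear running time without
    introducing run-to-run variation.
    """
    pts = np.asarray(points, dtype=float)
    if len(pts) == 0:
        raise ValueError("no points")
    idx = np.random.default_rng(0).permutation(len(pts))
    P = pts[idx]
    c, r = P[0], 0.0
    eps = 1e-12
    for i in range(1, len(P)):
        if np.hypot(*(P[i] - c)) > r * (1 + eps) + eps:
            c, r = _mec_with_one(P[: i + 1], P[i])
    return c, r


def _mec_with_one(P, p):
    c, r = p.copy(), 0.0
    eps = 1e-12
    for i in range(len(P)):
        q = P[i]
        if np.hypot(*(q - c)) > r * (1 + eps) + eps:
            if r == 0.0:
                c, r = (p + q) / 2.0, np.hypot(*(q - p)) / 2.0
            else:
                c, r = _mec_with_two(P[: i + 1], p, q)
    return c, r


def _mec_with_two(P, p, q):
    circ = ((p + q) / 2.0, np.hypot(*(q - p)) / 2.0)
    left = right = None
    pq = q - p
    eps = 1e-12
    for r_pt in P:
        if np.hypot(*(r_pt - circ[0])) <= circ[1] * (1 + eps) + eps:
            continue
        cross = pq[0] * (r_pt[1] - p[1]) - pq[1] * (r_pt[0] - p[0])
        cc = _circumcircle(p, q, r_pt)
        if cc is None:
            continue
        if cross > 0 and (left is None or _further(pq, p, cc[0], left[0]) > 0):
            left = cc
        elif cross < 0 and (right is None or _further(pq, p, cc[0], right[0]) < 0):
            right = cc
    if left is None and right is None:
        return circ
    if left is None:
        return right
    if right is None:
        return left
    return left if left[1] <= right[1] else right


def _further(pq, p, c_new, c_old):
    return pq[0] * (c_new[1] - c_old[1]) - pq[1] * (c_new[0] - c_old[0])


def _circumcircle(a, b, c):
    d = 2.0 * (a[0] * (b[1] - c[1]) + b[0] * (c[1] - a[1]) + c[0] * (a[1] - b[1]))
    if d == 0.0:
        return None
    ux = ((a @ a) * (b[1] - c[1]) + (b @ b) * (c[1] - a[1]) + (c @ c) * (a[1] - b[1])) / d
    uy = ((a @ a) * (c[0] - b[0]) + (b @ b) * (a[0] - c[0]) + (c @ c) * (b[0] - a[0])) / d
    centre = np.array([ux, uy])
    return centre, float(np.hypot(*(a - centre)))


def bounding_circle_diameter(contour: Contour) -> float:
    """Diameter of the minimum enclosing circle of the contour vertices.

    The polygon's extreme points are vertices, so the vertex set suffices.
    """
    _, r = min_enclosing_circle(contour.vertices)
    return float(2.0 * r)


def groove_depths(contour: Contour, depth_floor: float | None = None
                  ) -> tuple[float, float, int]:
    """(mean, max, count) of convex-hull pocket depths.

    For each hull edge, the pocket depth is the maximum perpendicular
    distance from the edge to the contour vertices lying between its two
    hull vertices along the contour.  Pockets shallower than ``depth_floor``
    (default 0.5% of the minimum-bounding-circle diameter) are ignored for
    the mean and count; the deepest pocket always defines the max.  A convex
    outline returns (0, 0, 0).
    """
    v = contour.vertices
    n = len(v)
    if depth_floor is None:
        depth_floor = DEFAULT_DEPTH_FLOOR_FRAC * bounding_circle_diameter(contour)
    hull_idx = np.sort(ConvexHull(v).vertices)  # contour order
    depths = []
    for a, b in zip(hull_idx, np.roll(hull_idx, -1)):
        lo, hi = a, b if b > a else b + n
        between = np.arange(lo + 1, hi) % n
        if len(between) == 0:
            continue
        pa, pb = v[a], v[b % n]
        edge = pb - pa
        elen = np.hypot(*edge)
        if elen == 0:
            continue
        rel = v[between] - pa
        d = np.abs(edge[0] * rel[:, 1] - edge[1] * rel[:, 0]) / elen
        depth = float(d.max())
        if depth > 0:
            depths.append(depth)
    if not depths:
        return 0.0, 0.0, 0
    depths = np.asarray(depths)
    significant = depths[depths > depth_floor]
    gmax = float(depths.max())
    if len(significant) == 0:
        return 0.0, gmax if gmax > depth_floor else 0.0, 0
    return float(significant.mean()), gmax, int(len(significant))


# ---------------------------------------------------------------------------
# full profile


@dataclass(frozen=True)
class EndocarpTraits:
    """22 A/B scalars (11 each) + 22 vertical-position scalars."""

    a_block: dict = field(default_factory=dict)
    b_block: dict = field(default_factory=dict)
    c_block: dict = field(default_factory=dict)
    a_present: bool = True
    b_present: bool = True
    c_present: bool = True

    def as_row(self) -> dict:
        row = {}
        for blk, suffix, present, keys in (
            (self.a_block, "A", self.a_present, _AB_KEYS),
            (self.b_block, "B", self.b_present, _AB_KEYS),
            (self.c_block, "C", self.c_present, _C_KEYS),
        ):
            if present:
                row.update({f"{k}-{suffix}": v for k, v in blk.items()})
            else:
                row.update({f"{k}-{suffix}": np.nan for k in keys})
        return row


_AB_KEYS = ["Area", "Perim", "Hght", "MaxTrDiam", "MinCntTr", "VerSym", "TrSym",
            "ShIdx", "Circ", "ApCur", "BasCur"]
_C_KEYS = ["Area", "Perim", "Hght", "MaxTrDiam", "MinCntTr", "VerSym", "TrSym",
           "ShIdx", "Circ", "EllipseMajor", "EllipseMinor", "ApCur", "BasCur",
           "StArConv", "MinCentCnt", "MaxCentCnt", "DiamInscrCir", "DiamMinBdCir",
           "GrooveMeanDepth", "GrooveMaxDepth", "GrooveCount", "PerimConvexity"]


def _ab_block(contour: Contour, params: EndocarpParams) -> dict:
    size = basic_size(contour)
    scores = shape_scores(contour, size, from_base=params.ver_sym_from_base)
    ap = mean_curvature(extreme_arc(contour, "apex", params.arc_fraction))
    bas = mean_curvature(extreme_arc(contour, "base", params.arc_fraction))
    return {
        "Area": size.area, "Perim": size.perimeter, "Hght": size.height,
        "MaxTrDiam": size.max_tr_diam, "MinCntTr": size.min_cnt_tr,
        "VerSym": scores.ver_sym, "TrSym": scores.tr_sym, "ShIdx": scores.sh_idx,
        "Circ": scores.circ, "ApCur": ap.kappa_mean, "BasCur": bas.kappa_mean,
    }


def vertical_block(contour: Contour, params: EndocarpParams = EndocarpParams()
                   ) -> EndocarpVertical:
    """The position-C sculpture descriptors as a typed record."""
    diam_bd = bounding_circle_diameter(contour)
    dmin, dmax = centre_distances(contour)
    gmean, gmax, gcount = groove_depths(
        contour, depth_floor=params.depth_floor_frac * diam_bd
    )
    hull = ConvexHull(contour.vertices)
    hull_perim = float(
        np.hypot(*np.diff(contour.vertices[np.append(hull.vertices, hull.vertices[0])],
                          axis=0).T).sum()
    )
    return EndocarpVertical(
        st_ar_conv=area_convexity(contour),
        min_cent_cnt=dmin,
        max_cent_cnt=dmax,
        diam_inscr_cir=inscribed_circle_diameter(
            contour, params.inscribed_resolution_frac
        ),
        diam_min_bd_cir=diam_bd,
        groove_mean_depth=gmean,
        groove_max_depth=gmax,
        groove_count=gcount,
        perim_convexity=hull_perim / contour.perimeter(),
        centre=tuple(contour.centroid()),
    )


def endocarp_profile(contour_a: Contour | None, contour_b: Contour | None,
                     contour_c: Contour | None,
                     params: EndocarpParams = EndocarpParams()) -> EndocarpTraits:
    """Assemble the endocarp record from the A, B and vertical (C) views.

    Any missing view leaves its block flagged absent; the others are still
    computed.  Deterministic for fixed inputs.
    """
    a_block = _ab_block(contour_a, params) if contour_a is not None else {}
    b_block = _ab_block(contour_b, params) if contour_b is not None else {}
    c_block = {}
    if contour_c is not None:
        size = basic_size(contour_c)
        scores = shape_scores(contour_c, size, from_base=params.ver_sym_from_base)
        ap = mean_curvature(extreme_arc(contour_c, "apex", params.arc_fraction))
        bas = mean_curvature(extreme_arc(contour_c, "base", params.arc_fraction))
        vert = vertical_block(contour_c, params)
        c_block = {
            "Area": size.area, "Perim": size.perimeter, "Hght": size.height,
            "MaxTrDiam": size.max_tr_diam, "MinCntTr": size.min_cnt_tr,
            "VerSym": scores.ver_sym, "TrSym": scores.tr_sym, "ShIdx": scores.sh_idx,
            "Circ": scores.circ, "EllipseMajor": scores.ellipse_major,
            "EllipseMinor": scores.ellipse_minor, "ApCur": ap.kappa_mean,
            "BasCur": bas.kappa_mean, "StArConv": vert.st_ar_conv,
            "MinCentCnt": vert.min_cent_cnt, "MaxCentCnt": vert.max_cent_cnt,
            "DiamInscrCir": vert.diam_inscr_cir, "DiamMinBdCir": vert.diam_min_bd_cir,
            "GrooveMeanDepth": vert.groove_mean_depth,
            "GrooveMaxDepth": vert.groove_max_depth,
            "GrooveCount": vert.groove_count,
            "PerimConvexity": vert.perim_convexity,
        }
    return EndocarpTraits(
        a_block=a_block, b_block=b_block, c_block=c_block,
        a_present=contour_a is not None, b_present=contour_b is not None,
        c_present=contour_c is not None,
    )
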