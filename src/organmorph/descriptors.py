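"""Size, symmetry, shape and curvature descriptors shared by all organs.

All descriptors are purely geometric functions of a calibrated, oriented
:class:`~organmorph.contour.Contour` (base at minimum y, apex at maximum y):

* height ``Hght`` — vertical extent between base A and apex B;
* ``MaxTrDiam`` — the longest horizontal chord anywhere across the shape,
  with endpoints C, D and its intersection O with the vertical through the
  midpoint of A–B;
* vertical symmetry ``VerSym`` = |O − B| / Hght (0.5 for a top/bottom
  symmetric outline), transversal symmetry ``TrSym`` = MinCntTr / MaxTrDiam
  (0.5 for a left/right symmetric one);
* shape index ``ShIdx`` = Hght / MaxTrDiam, circularity
  ``Circ`` = 4·pi·Area / Perimeter², the moment-equivalent ellipse axes;
* mean apex/base curvature from circumscribed circles of vertex triples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .contour import Contour
from .errors import ArcTooShortError, DegenerateObjectError

__all__ = [
    "BasicSize",
    "ShapeScores",
    "Arc",
    "CurvatureScore",
    "basic_size",
    "symmetry",
    "shape_scores",
    "extreme_arc",
    "mean_curvature",
    "signed_curvature_profile",
    "horizontal_chords",
    "max_transverse_diameter",
]

DEFAULT_ARC_FRACTION = 0.05  # extent of the apex/base/tip arc


@dataclass(frozen=True)
class BasicSize:
    area: float
    perimeter: float
    height: float
    max_tr_diam: float
    min_cnt_tr: float
    chord_endpoints: tuple  # ((xC, y), (xD, y))
    axis_intersection: tuple  # O = (x_mid(A,B), y of the chord)
    base_point: tuple  # A, topmost
    apex_point: tuple  # B, bottommost


@dataclass(frozen=True)
class ShapeScores:
    ver_sym: float
    tr_sym: float
    sh_idx: float
    circ: float
    ellipse_major: float
    ellipse_minor: float


@dataclass(frozen=True)
class Arc:
    """An open, contiguous vertex run of a parent contour around an extreme."""

    vertices: np.ndarray
    anchor_index: int  # index of the extreme point within `vertices`

    def length(self) -> float:
        d = np.diff(self.vertices, axis=0)
        return float(np.hypot(d[:, 0], d[:, 1]).sum())


@dataclass(frozen=True)
class CurvatureScore:
    kappa_mean: float  # cm^-1 on calibrated contours
    arc: Arc
    fraction: float


def extreme_vertex_index(vertices: np.ndarray, which: str,
                         tol: float = 1e-4) -> int:
    """Index of the apex ("apex"/"tip", max y) or base ("base", min y) vertex.

    On rasterized contours the extreme region can be flat to sub-pixel
    ripple (a disc's pole), making a bare argmax land wherever the noise
    peaks; all vertices within ``tol`` of the height of the extreme are
    treated as tied and the centre of the tied run (circularly contiguous)
    is returned.
    """
    y = vertices[:, 1]
    h = y.max() - y.min()
    if which in ("apex", "tip"):
        tied = np.flatnonzero(y >= y.max() - tol * h)
    elif which == "base":
        tied = np.flatnonzero(y <= y.min() + tol * h)
    else:
        raise ValueError(f"unknown extreme {which!r}")
    if len(tied) == 1:
        return int(tied[0])
    n = len(vertices)
    # unwrap a run that straddles index 0
    if tied[0] == 0 and tied[-1] == n - 1:
        gaps = np.flatnonzero(np.diff(tied) > 1)
        if len(gaps):
            start = tied[gaps[0] + 1]
            tied = np.concatenate([tied[gaps[0] + 1:], tied[: gaps[0] + 1] + n])
    return int(tied[len(tied) // 2] % n)


# ---------------------------------------------------------------------------
# horizontal chord machinery


def horizontal_chords(vertices: np.ndarray, y: float) -> list[tuple[float, float]]:
    """Intersection segments of the horizontal line at ``y`` with the polygon.

    Even-odd scanline rule with a half-open vertex convention, returning
    sorted (x_left, x_right) pairs.  Levels passing exactly through a vertex
    are handled consistently; degenerate zero-length segments are dropped.
    """
    v = vertices
    w = np.roll(v, -1, axis=0)
    below_v = v[:, 1] <= y
    below_w = w[:, 1] <= y
    crossing = below_v != below_w
    if not crossing.any():
        return []
    pv, pw = v[crossing], w[crossing]
    t = (y - pv[:, 1]) / (pw[:, 1] - pv[:, 1])
    xs = np.sort(pv[:, 0] + t * (pw[:, 0] - pv[:, 0]))
    pairs = [(xs[i], xs[i + 1]) for i in range(0, len(xs) - 1, 2)]
    return [(a, b) for a, b in pairs if b > a]


def _longest_chord_at(vertices: np.ndarray, y: float) -> tuple[float, float, float]:
    """(length, x_left, x_right) of the longest single segment at level y."""
    segs = horizontal_chords(vertices, y)
    if not segs:
        return 0.0, np.nan, np.nan
    a, b = max(segs, key=lambda s: s[1] - s[0])
    return b - a, a, b


def max_transverse_diameter(
    contour: Contour, n_scan: int = 1024, n_refine: int = 64,
    tie_tol: float = 1e-4
) -> tuple[float, float, float, float]:
    """Longest horizontal chord: returns (length, x_left, x_right, y_level).

    Coarse scan over ``n_scan`` evenly spaced levels, then a local
    refinement pass.  Exact ties never occur on rasterized contours, so any
    chord within ``tie_tol`` (relative) of the maximum counts as tied and
    the tie resolves to the centre of the tied plateau — on a disc, whose
    equatorial width profile is flat to sub-pixel ripple, this reports the
    equator rather than wherever the noise happens to peak.
    """
    v = contour.vertices
    y0, y1 = v[:, 1].min(), v[:, 1].max()
    h = y1 - y0
    if h <= 0:
        raise DegenerateObjectError("flat contour")

    def pick(levels, lengths):
        lmax = lengths.max()
        tied = np.flatnonzero(lengths >= (1.0 - tie_tol) * lmax)
        centre = levels[tied].mean()
        return tied[np.argmin(np.abs(levels[tied] - centre))]

    levels = np.linspace(y0 + 1e-9 * h, y1 - 1e-9 * h, n_scan)
    lengths = np.array([_longest_chord_at(v, yy)[0] for yy in levels])
    best = pick(levels, lengths)
    lo = levels[max(best - 1, 0)]
    hi = levels[min(best + 1, n_scan - 1)]
    fine = np.linspace(lo, hi, n_refine)
    fine_chords = [_longest_chord_at(v, yy) for yy in fine]
    fine_lengths = np.array([c[0] for c in fine_chords])
    j = pick(fine, fine_lengths)
    length, xa, xb = fine_chords[j]
    return float(length), float(xa), float(xb), float(fine[j])


# ---------------------------------------------------------------------------
# descriptor operations


def basic_size(contour: Contour) -> BasicSize:
    """Area, perimeter, height and maximum-transverse-diameter geometry."""
    v = contour.vertices
    base = v[extreme_vertex_index(v, "base")]
    apex = v[extreme_vertex_index(v, "apex")]
    height = float(apex[1] - base[1])
    if height <= 0:
        raise DegenerateObjectError("zero-height contour")
    length, xa, xb, y_chord = max_transverse_diameter(contour)
    x_mid = (base[0] + apex[0]) / 2.0  # vertical axis through midpoint of A-B
    o_point = (float(x_mid), y_chord)
    min_cnt_tr = float(min(abs(x_mid - xa), abs(xb - x_mid)))
    return BasicSize(
        area=contour.area(),
        perimeter=contour.perimeter(),
        height=height,
        max_tr_diam=length,
        min_cnt_tr=min_cnt_tr,
        chord_endpoints=((float(xa), y_chord), (float(xb), y_chord)),
        axis_intersection=o_point,
        base_point=(float(base[0]), float(base[1])),
        apex_point=(float(apex[0]), float(apex[1])),
    )


def symmetry(size: BasicSize, from_base: bool = False) -> tuple[float, float]:
    """(VerSym, TrSym).

    VerSym is the widest chord's relative position along the height axis,
    measured from the apex end by default (``from_base=True`` flips the
    reference end); TrSym is MinCntTr / MaxTrDiam.
    """
    y_o = size.axis_intersection[1]
    if from_base:
        ver = abs(y_o - size.base_point[1]) / size.height
    else:
        ver = abs(size.apex_point[1] - y_o) / size.height
    tr = size.min_cnt_tr / size.max_tr_diam
    return float(ver), float(tr)


def _region_moments(v: np.ndarray) -> np.ndarray:
    """Central second-moment (covariance) matrix of the enclosed region."""
    w = np.roll(v, -1, axis=0)
    cross = v[:, 0] * w[:, 1] - w[:, 0] * v[:, 1]
    a = cross.sum() / 2.0
    cx = ((v[:, 0] + w[:, 0]) * cross).sum() / (6 * a)
    cy = ((v[:, 1] + w[:, 1]) * cross).sum() / (6 * a)
    ixx = ((v[:, 0] ** 2 + v[:, 0] * w[:, 0] + w[:, 0] ** 2) * cross).sum() / 12.0
    iyy = ((v[:, 1] ** 2 + v[:, 1] * w[:, 1] + w[:, 1] ** 2) * cross).sum() / 12.0
    ixy = (
        (v[:, 0] * w[:, 1] + 2 * v[:, 0] * v[:, 1] + 2 * w[:, 0] * w[:, 1] + w[:, 0] * v[:, 1])
        * cross
    ).sum() / 24.0
    mu = np.array([[ixx / a - cx**2, ixy / a - cx * cy],
                   [ixy / a - cx * cy, iyy / a - cy**2]])
    return mu


def shape_scores(contour: Contour, size: BasicSize, from_base: bool = False) -> ShapeScores:
    """Symmetries, shape index, circularity and moment-equivalent ellipse.

    The ellipse axes are the full axes of the ellipse with the same area and
    second central moments as the enclosed region (4·sqrt of the covariance
    eigenvalues); for any true ellipse this recovers 2a and 2b exactly.
    """
    ver, tr = symmetry(size, from_base=from_base)
    circ = 4.0 * np.pi * size.area / size.perimeter**2
    mu = _region_moments(contour.vertices)
    evals = np.linalg.eigvalsh(mu)
    evals = np.clip(evals, 0.0, None)
    minor, major = 4.0 * np.sqrt(evals)
    return ShapeScores(
        ver_sym=ver,
        tr_sym=tr,
        sh_idx=size.height / size.max_tr_diam,
        circ=float(circ),
        ellipse_major=float(major),
        ellipse_minor=float(minor),
    )


def extreme_arc(contour: Contour, which: str = "apex",
                fraction: float = DEFAULT_ARC_FRACTION) -> Arc:
    """The contiguous vertex run centred (by arc length) on an extreme point.

    ``which`` is "apex" (maximum y), "base" (minimum y) or "tip" (the leaf
    synonym of apex).  Assumes a uniformly resampled contour, on which an
    index-centred window is an arc-length-centred one.
    """
    if not (0.0 < fraction <= 0.2):
        raise ValueError("fraction must be in (0, 0.2]")
    v = contour.vertices
    n = len(v)
    centre = extreme_vertex_index(v, which)
    m = int(round(fraction * n))
    m = max(m, 3)
    half = m // 2
    idx = (np.arange(centre - half, centre - half + m)) % n
    return Arc(vertices=v[idx].copy(), anchor_index=half)


def _triple_curvature(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Signed curvature of the circumscribed circle of triples (a, b, c).

    Sign is positive where the polygon (positive shoelace order) is locally
    convex.  kappa = 4 * signed triangle area / product of side lengths.
    """
    ab = b - a
    bc = c - b
    ca = a - c
    cross = ab[..., 0] * bc[..., 1] - ab[..., 1] * bc[..., 0]
    denom = (
        np.hypot(ab[..., 0], ab[..., 1])
        * np.hypot(bc[..., 0], bc[..., 1])
        * np.hypot(ca[..., 0], ca[..., 1])
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        k = np.where(denom > 0, 2.0 * cross / np.where(denom > 0, denom, 1.0), 0.0)
    return k


def mean_curvature(arc: Arc) -> CurvatureScore:
    """Mean unsigned curvature over an arc.

    Discrete curvature at each interior vertex is 1/R of the circumscribed
    circle of the vertex triple (i-s, i, i+s) with stride
    ``s = max(1, len // 15)``; the score is the arithmetic mean of |kappa|.
    Equals 1/R on circular arcs and 0 on straight runs.
    """
    v = arc.vertices
    n = len(v)
    if n < 7:
        raise ArcTooShortError(f"need >= 7 vertices, got {n}")
    s = max(1, n // 15)
    i = np.arange(s, n - s)
    k = _triple_curvature(v[i - s], v[i], v[i + s])
    frac = n  # informational
    return CurvatureScore(kappa_mean=float(np.mean(np.abs(k))), arc=arc,
                          fraction=float(frac))


def signed_curvature_profile(contour: Contour, spacing_frac: float = 0.01) -> np.ndarray:
    """Signed curvature at every vertex, neighbours taken ``spacing_frac·n`` apart.

    Positive where the outline is locally convex.  Used internally for
    nipple detection; the spacing acts as a scale parameter that suppresses
    residual rasterization noise.
    """
    v = contour.vertices
    n = len(v)
    s = max(2, int(round(spacing_frac * n)))
    i = np.arange(n)
    return _triple_curvature(v[(i - s) % n], v[i], v[(i + s) % n])
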