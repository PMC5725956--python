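"""Leaf-specific analysis: petiole split, blade metrics, tip curvature.

Leaves are scanned flat in a single view, petiole end up (the base).  The
petiole is separated from the blade on the horizontal width profile w(y):
it is the maximal contiguous run of stations, starting at the base, whose
width stays below ``width_frac_cut`` times the maximum width, provided the
run lasts at least ``min_run`` of the total height (which excludes the
naturally narrow tip of a petiole-free blade).  Shape descriptors are then
computed on the blade; height and perimeter describe the whole leaf.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from shapely.geometry import Polygon, box

from .contour import Contour, smooth_resample
from .descriptors import (
    basic_size,
    extreme_arc,
    horizontal_chords,
    mean_curvature,
    shape_scores,
)
from .errors import DegenerateObjectError

__all__ = ["LeafParams", "LeafTraits", "split_petiole", "leaf_profile", "width_profile"]

DEFAULT_WIDTH_FRAC_CUT = 0.15
DEFAULT_MIN_RUN = 0.02


@dataclass(frozen=True)
class LeafParams:
    width_frac_cut: float = DEFAULT_WIDTH_FRAC_CUT
    min_run: float = DEFAULT_MIN_RUN
    arc_fraction: float = 0.05
    ver_sym_from_base: bool = False
    n_stations: int = 512


@dataclass(frozen=True)
class LeafTraits:
    """16 leaf scalars (blade descriptors + whole-leaf size + petiole)."""

    area: float  # blade area, cm^2
    perimeter: float  # whole-leaf perimeter, cm
    hght: float  # whole-leaf height, cm
    blade_hgt: float
    max_tr_diam: float  # blade width
    min_cnt_tr: float
    ver_sym: float  # whole-leaf
    width_position: float  # VerSym of the blade
    tr_sym: float
    sh_idx: float  # blade_hgt / max_tr_diam
    circ: float  # whole leaf
    ellipse_major: float
    ellipse_minor: float
    tip_cur: float
    petiole_hgt: float
    petiole_area: float

    def as_row(self) -> dict:
        return {
            "Area": self.area, "Perimeter": self.perimeter, "Hght": self.hght,
            "BladeHgt": self.blade_hgt, "MaxTrDiam": self.max_tr_diam,
            "MinCntTr": self.min_cnt_tr, "VerSym": self.ver_sym,
            "WidthPos": self.width_position, "TrSym": self.tr_sym,
            "ShIdx": self.sh_idx, "Circ": self.circ,
            "EllipseMajor": self.ellipse_major, "EllipseMinor": self.ellipse_minor,
            "TipCur": self.tip_cur, "PetioleHgt": self.petiole_hgt,
            "PetioleArea": self.petiole_area,
        }


def width_profile(contour: Contour, n_stations: int = 512) -> tuple[np.ndarray, np.ndarray]:
    """(y levels, widths): longest single horizontal chord at each station.

    Stations are the centres of ``n_stations`` equal y-bins spanning the
    contour's height.
    """
    v = contour.vertices
    y0, y1 = v[:, 1].min(), v[:, 1].max()
    edges = np.linspace(y0, y1, n_stations + 1)
    levels = (edges[:-1] + edges[1:]) / 2.0
    widths = np.empty(n_stations)
    for i, yy in enumerate(levels):
        segs = horizontal_chords(v, yy)
        widths[i] = max((b - a for a, b in segs), default=0.0)
    return levels, widths


def split_petiole(
    contour: Contour,
    width_frac_cut: float = DEFAULT_WIDTH_FRAC_CUT,
    min_run: float = DEFAULT_MIN_RUN,
    n_stations: int = 512,
) -> tuple[Contour, float, float]:
    """Split a leaf contour into (blade, petiole_hgt, petiole_area).

    No qualifying narrow run at the base (petiole absent, or one wider than
    the threshold) returns the whole contour as the blade with zero petiole
    height and area.
    """
    if not (0 < width_frac_cut < 0.5):
        raise ValueError("width_frac_cut must be in (0, 0.5)")
    levels, widths = width_profile(contour, n_stations)
    max_w = widths.max()
    if max_w <= 0:
        raise DegenerateObjectError("zero-width contour")
    narrow = widths < width_frac_cut * max_w
    k = 0
    while k < n_stations and narrow[k]:
        k += 1
    v = contour.vertices
    y0, y1 = v[:, 1].min(), v[:, 1].max()
    height = y1 - y0
    dy = height / n_stations
    run = k * dy
    if k == 0 or k >= n_stations // 2 or run < min_run * height:
        return contour, 0.0, 0.0
    # Refine the cut to the flare point.  The raw run extends past the true
    # stem/blade junction until the blade widens to the cut threshold, which
    # overcounts a cap sliver for narrow stems; the junction is located where
    # the width first rises clearly above the stem's own typical width.
    w_stem = float(np.median(widths[: max(1, k // 2)]))
    flare = max(1.25 * w_stem, w_stem + 0.1 * (width_frac_cut * max_w - w_stem))
    k_ref = 0
    while k_ref < k and widths[k_ref] <= flare:
        k_ref += 1
    if k_ref > 0:
        k = k_ref
        run = k * dy
    y_cut = y0 + run
    whole = Polygon(v)
    pad = 0.05 * height
    blade_geom = whole.intersection(
        box(v[:, 0].min() - pad, y_cut, v[:, 0].max() + pad, y1 + pad)
    )
    if blade_geom.geom_type == "MultiPolygon":
        blade_geom = max(blade_geom.geoms, key=lambda g: g.area)
    if blade_geom.is_empty or blade_geom.geom_type != "Polygon":
        raise DegenerateObjectError("petiole split left no blade")
    bv = np.asarray(blade_geom.exterior.coords)[:-1]
    blade = Contour(bv, pixels_per_cm=contour.pixels_per_cm,
                    orientation=contour.orientation, calibrated=contour.calibrated)
    blade = smooth_resample(blade, window_frac=0.0, n_out=max(len(v), 64))
    petiole_area = whole.area - blade_geom.area
    return blade, float(run), float(petiole_area)


def leaf_profile(contour: Contour, params: LeafParams = LeafParams()) -> LeafTraits:
    """Assemble the 16-scalar leaf record from a single oriented contour.

    The contour must be calibrated, petiole end at the top (base).  Shape
    descriptors come from the blade after the petiole split; tip curvature
    from the arc around the blade's apex (opposite the petiole).
    """
    blade, petiole_hgt, petiole_area = split_petiole(
        contour, params.width_frac_cut, params.min_run, params.n_stations
    )
    whole_size = basic_size(contour)
    blade_size = basic_size(blade)
    whole_scores = shape_scores(contour, whole_size, from_base=params.ver_sym_from_base)
    blade_scores = shape_scores(blade, blade_size, from_base=params.ver_sym_from_base)
    tip = mean_curvature(extreme_arc(blade, "tip", params.arc_fraction))
    return LeafTraits(
        area=blade_size.area,
        perimeter=whole_size.perimeter,
        hght=whole_size.height,
        blade_hgt=blade_size.height,
        max_tr_diam=blade_size.max_tr_diam,
        min_cnt_tr=blade_size.min_cnt_tr,
        ver_sym=whole_scores.ver_sym,
        width_position=blade_scores.ver_sym,
        tr_sym=blade_scores.tr_sym,
        sh_idx=blade_size.height / blade_size.max_tr_diam,
        circ=whole_scores.circ,
        ellipse_major=blade_scores.ellipse_major,
        ellipse_minor=blade_scores.ellipse_minor,
        tip_cur=tip.kappa_mean,
        petiole_hgt=petiole_hgt,
        petiole_area=petiole_area,
    )
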