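"""Fruit-specific analysis: nipple geometry and the two-position profile.

Some cultivars carry a *nipple* — a small protrusion at the fruit apex that
is a diagnostic varietal character.  Detection works on the signed
curvature profile of the contour: a nipple shows up as a high-curvature
peak at the apex flanked on both sides by curvature *shoulders* (local
minima, often concave) where the protrusion meets the fruit body.  The
shoulders E and F anchor the chord that closes the nipple arc E–B–F, from
which height, area and arc length are measured.

A fruit is photographed in two poses: position A (maximal asymmetry) and
position B (A rotated 90 deg about the vertical axis); the profile gathers
descriptors from both.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .contour import Contour
from .descriptors import (
    basic_size,
    extreme_arc,
    extreme_vertex_index,
    mean_curvature,
    shape_scores,
    signed_curvature_profile,
)

__all__ = ["NippleGeometry", "FruitParams", "FruitTraits", "detect_nipple", "fruit_profile"]

DEFAULT_KAPPA_RATIO = 3.0
DEFAULT_SEARCH_FRAC = 0.25


@dataclass(frozen=True)
class NippleGeometry:
    present: bool
    height: float = 0.0  # perpendicular distance from apex B to chord E-F
    area: float = 0.0  # enclosed by arc E-B-F and the chord
    upper_length: float = 0.0  # arc length of E-B-F
    e_point: tuple = (0.0, 0.0)
    f_point: tuple = (0.0, 0.0)

    @property
    def index(self) -> int:
        """NippleIdx: 1 = present, 0 = absent."""
        return int(self.present)


@dataclass(frozen=True)
class FruitParams:
    """Tunables of the fruit profile; defaults calibrated on the synthetic
    bump-fixture family (the original trial-and-error threshold is not a
    published constant)."""

    kappa_ratio_threshold: float = DEFAULT_KAPPA_RATIO
    search_frac: float = DEFAULT_SEARCH_FRAC
    arc_fraction: float = 0.05
    ver_sym_from_base: bool = False
    curvature_spacing_frac: float = 0.02
    shoulder_prominence_frac: float = 0.5  # x median |kappa|


def detect_nipple(
    contour: Contour,
    kappa_ratio_threshold: float = DEFAULT_KAPPA_RATIO,
    search_frac: float = DEFAULT_SEARCH_FRAC,
    curvature_spacing_frac: float = 0.02,
    shoulder_prominence_frac: float = 0.5,
) -> NippleGeometry:
    """Detect and measure an apex nipple on an oriented, calibrated contour.

    Walking outward from the apex B on each side, the first prominent local
    minimum of signed curvature is a *shoulder* (the protrusion/body
    junction).  A nipple is declared when both shoulders exist inside the
    search window (``search_frac`` of the contour centred on B) and the
    curvature peak between them reaches ``kappa_ratio_threshold`` times the
    median |kappa| of the whole contour — i.e. the apex is set off from the
    body, not merely its most curved point.  Absent nipple: all-zero
    geometry.  Borderline profiles resolve by threshold, never by exception.
    """
    if not kappa_ratio_threshold > 1:
        raise ValueError("kappa_ratio_threshold must be > 1")
    if not (0 < search_frac <= 0.3):
        raise ValueError("search_frac must be in (0, 0.3]")
    v = contour.vertices
    n = len(v)
    kappa = signed_curvature_profile(contour, spacing_frac=curvature_spacing_frac)
    med = float(np.median(np.abs(kappa)))
    if med == 0:
        return NippleGeometry(present=False)
    i_apex = extreme_vertex_index(v, "apex")
    half = max(3, int(round(search_frac * n / 2)))
    prominence = shoulder_prominence_frac * med

    shoulders = []
    for side in (+1, -1):
        idx = (i_apex + side * np.arange(0, half + 1)) % n
        prof = kappa[idx]
        # first prominent local minimum walking outward from B
        minima, _ = find_peaks(-prof, prominence=prominence)
        if len(minima) == 0:
            return NippleGeometry(present=False)
        shoulders.append(int(idx[minima[0]]))

    i_e, i_f = shoulders  # +side first, then -side
    # arc E..B..F through the apex (indices from i_f to i_e passing i_apex)
    arc_idx = _circular_range(i_f, i_e, n)
    if i_apex not in arc_idx:
        return NippleGeometry(present=False)
    arc = v[arc_idx]
    peak = float(np.max(kappa[arc_idx]))
    if peak < kappa_ratio_threshold * med:
        return NippleGeometry(present=False)

    e, f = v[i_e], v[i_f]
    chord = f - e
    clen = np.hypot(*chord)
    if clen == 0:
        return NippleGeometry(present=False)
    apex = v[i_apex]
    rel = apex - e
    height = abs(chord[0] * rel[1] - chord[1] * rel[0]) / clen
    poly = np.vstack([arc])  # closed implicitly by the chord F->E
    w = np.roll(poly, -1, axis=0)
    area = abs((poly[:, 0] * w[:, 1] - w[:, 0] * poly[:, 1]).sum() / 2.0)
    d = np.diff(arc, axis=0)
    upper_length = float(np.hypot(d[:, 0], d[:, 1]).sum())
    return NippleGeometry(
        present=True,
        height=float(height),
        area=float(area),
        upper_length=upper_length,
        e_point=(float(e[0]), float(e[1])),
        f_point=(float(f[0]), float(f[1])),
    )


def _circular_range(i: int, j: int, n: int) -> np.ndarray:
    """Indices i..j walking forward (mod n), inclusive."""
    if j >= i:
        return np.arange(i, j + 1)
    return np.concatenate([np.arange(i, n), np.arange(0, j + 1)])


# ---------------------------------------------------------------------------
# full fruit profile


@dataclass(frozen=True)
class FruitTraits:
    """The fruit descriptor record: 24 core scalars across positions A and B.

    A block: Area, Perim, Hght, MaxTrDiam, MinCntTr, VerSym, TrSym, ShIdx,
    Circ, EllipseMajor, EllipseMinor, ApCur, BasCur (13) + NippleIdx;
    B block: Area, Perim, Hght, MaxTrDiam, ShIdx, VerSym, TrSym, Circ,
    ApCur, BasCur (10).  Nipple height/area/arc-length ride along as
    supplementary columns.
    """

    a_block: dict = field(default_factory=dict)
    b_block: dict = field(default_factory=dict)
    nipple: NippleGeometry = NippleGeometry(present=False)
    b_present: bool = True

    CORE_COUNT = 24

    def as_row(self) -> dict:
        row = {f"{k}-A": v for k, v in self.a_block.items()}
        row["NippleIdx-A"] = self.nipple.index
        row["NippleHght-A"] = self.nipple.height
        row["NippleArea-A"] = self.nipple.area
        row["NippleArcLen-A"] = self.nipple.upper_length
        if self.b_present:
            row.update({f"{k}-B": v for k, v in self.b_block.items()})
        else:
            row.update({f"{k}-B": np.nan for k in _B_KEYS})
        return row


_A_KEYS = ["Area", "Perim", "Hght", "MaxTrDiam", "MinCntTr", "VerSym", "TrSym",
           "ShIdx", "Circ", "EllipseMajor", "EllipseMinor", "ApCur", "BasCur"]
_B_KEYS = ["Area", "Perim", "Hght", "MaxTrDiam", "ShIdx", "VerSym", "TrSym",
           "Circ", "ApCur", "BasCur"]


def _common_block(contour: Contour, params: FruitParams, keys) -> dict:
    size = basic_size(contour)
    scores = shape_scores(contour, size, from_base=params.ver_sym_from_base)
    ap = mean_curvature(extreme_arc(contour, "apex", params.arc_fraction))
    bas = mean_curvature(extreme_arc(contour, "base", params.arc_fraction))
    full = {
        "Area": size.area, "Perim": size.perimeter, "Hght": size.height,
        "MaxTrDiam": size.max_tr_diam, "MinCntTr": size.min_cnt_tr,
        "VerSym": scores.ver_sym, "TrSym": scores.tr_sym,
        "ShIdx": scores.sh_idx, "Circ": scores.circ,
        "EllipseMajor": scores.ellipse_major, "EllipseMinor": scores.ellipse_minor,
        "ApCur": ap.kappa_mean, "BasCur": bas.kappa_mean,
    }
    return {k: full[k] for k in keys}


def fruit_profile(contour_a: Contour, contour_b: Contour | None = None,
                  params: FruitParams = FruitParams()) -> FruitTraits:
    """Assemble the full fruit record from position-A and -B contours.

    Both contours must be oriented base-up and calibrated.  A missing
    position-B contour leaves the B block flagged absent (NaN columns)
    rather than failing the specimen.  Deterministic for fixed inputs.
    """
    a_block = _common_block(contour_a, params, _A_KEYS)
    nipple = detect_nipple(
        contour_a,
        kappa_ratio_threshold=params.kappa_ratio_threshold,
        search_frac=params.search_frac,
        curvature_spacing_frac=params.curvature_spacing_frac,
        shoulder_prominence_frac=params.shoulder_prominence_frac,
    )
    if contour_b is not None:
        b_block = _common_block(contour_b, params, _B_KEYS)
        return FruitTraits(a_block=a_block, b_block=b_block, nipple=nipple)
    return FruitTraits(a_block=a_block, b_block={}, nipple=nipple, b_present=False)
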