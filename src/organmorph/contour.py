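"""Closed polygonal contours: tracing, smoothing, calibration, orientation.

The universal shape representation downstream of segmentation is a simple
closed polygon whose vertices are boundary points, stored in an image frame
(x right, y down).  Under this frame the *base* of an organ photographed
base-up is the topmost point (minimum y) and the *apex* the bottommost
(maximum y).  Vertices are ordered so the shoelace signed area is positive;
that single stored convention is what every descriptor relies on.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from skimage import measure

from .errors import DegenerateObjectError, InvalidCalibrationError, InvalidMaskError

__all__ = [
    "Contour",
    "trace_boundary",
    "smooth_resample",
    "calibrate",
    "normalize_orientation",
    "read_contour_csv",
]

#: defaults tuned for >= 600 dpi silhouettes: heavy enough to kill pixel
#: stair-stepping, light enough to preserve nipple-scale apex features
DEFAULT_WINDOW_FRAC = 0.01
DEFAULT_N_OUT = 1000


@dataclass(frozen=True)
class Contour:
    """A simple closed polygon in the image frame.

    ``vertices`` is an (n, 2) float array of (x, y) pairs; the closing edge
    from the last vertex back to the first is implicit.  Units are pixels
    until :func:`calibrate` divides by ``pixels_per_cm``, after which they
    are cm.  ``orientation`` records whether the polygon still sits as
    imaged or has been rotated to principal axes.
    """

    vertices: np.ndarray
    pixels_per_cm: float = 1.0
    orientation: str = "image-frame"
    calibrated: bool = field(default=False)

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 3:
            raise DegenerateObjectError(
                f"a contour needs >= 3 (x, y) vertices, got shape {v.shape}"
            )
        object.__setattr__(self, "vertices", v)
        if _signed_area(v) < 0:
            object.__setattr__(self, "vertices", v[::-1].copy())

    # -- elementary geometry -------------------------------------------------

    @property
    def n_points(self) -> int:
        return len(self.vertices)

    @property
    def x(self) -> np.ndarray:
        return self.vertices[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.vertices[:, 1]

    def signed_area(self) -> float:
        return _signed_area(self.vertices)

    def area(self) -> float:
        return abs(self.signed_area())

    def edge_lengths(self) -> np.ndarray:
        d = np.diff(np.vstack([self.vertices, self.vertices[:1]]), axis=0)
        return np.hypot(d[:, 0], d[:, 1])

    def perimeter(self) -> float:
        return float(self.edge_lengths().sum())

    def centroid(self) -> np.ndarray:
        """Area centroid of the enclosed region (not the vertex mean)."""
        v = self.vertices
        w = np.roll(v, -1, axis=0)
        cross = v[:, 0] * w[:, 1] - w[:, 0] * v[:, 1]
        a = cross.sum() / 2.0
        cx = ((v[:, 0] + w[:, 0]) * cross).sum() / (6.0 * a)
        cy = ((v[:, 1] + w[:, 1]) * cross).sum() / (6.0 * a)
        return np.array([cx, cy])

    def to_csv(self, path) -> None:
        np.savetxt(path, self.vertices, delimiter=",", header="x,y", comments="")

    def __eq__(self, other) -> bool:  # dataclass eq breaks on arrays
        if not isinstance(other, Contour):
            return NotImplemented
        return (
            self.vertices.shape == other.vertices.shape
            and bool(np.all(self.vertices == other.vertices))
            and self.pixels_per_cm == other.pixels_per_cm
            and self.orientation == other.orientation
        )


def _signed_area(v: np.ndarray) -> float:
    w = np.roll(v, -1, axis=0)
    return float((v[:, 0] * w[:, 1] - w[:, 0] * v[:, 1]).sum() / 2.0)


def read_contour_csv(path, pixels_per_cm: float = 1.0, calibrated: bool = True) -> Contour:
    """Load a contour from a plain x,y CSV (one vertex per row, cm)."""
    v = np.loadtxt(path, delimiter=",", skiprows=1)
    if len(v) > 1 and np.allclose(v[0], v[-1]):
        v = v[:-1]  # tolerate an explicit closing point
    return Contour(v, pixels_per_cm=pixels_per_cm, calibrated=calibrated)


# ---------------------------------------------------------------------------
# tracing


def trace_boundary(mask: np.ndarray) -> Contour:
    """Trace the outer boundary of a clean binary mask as a closed polygon.

    Marching squares at the 0.5 iso-level of the padded mask: the polygon
    runs along pixel edges at half-pixel resolution, so every boundary pixel
    of the object lies within one pixel of the polygon.  Coordinates are
    returned in (x, y) = (col, row) pixel units, uncalibrated.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise InvalidMaskError("empty mask")
    if mask.sum() < 3:
        raise DegenerateObjectError("object of < 3 pixels cannot form a contour")
    n_comp = measure.label(mask, connectivity=2).max()
    if n_comp != 1:
        raise InvalidMaskError(f"mask has {n_comp} components; run clean_mask first")
    padded = np.pad(mask, 1).astype(float)
    rings = measure.find_contours(padded, 0.5)
    ring = max(rings, key=len)  # outer ring has the most points
    ring = ring[:-1]  # drop duplicated closing point
    if len(ring) < 3:
        raise DegenerateObjectError("object too small to form a closed contour")
    xy = np.column_stack([ring[:, 1] - 1.0, ring[:, 0] - 1.0])  # undo pad, (x,y)
    return Contour(xy)


# ---------------------------------------------------------------------------
# smoothing / resampling


def smooth_resample(
    contour: Contour,
    window_frac: float = DEFAULT_WINDOW_FRAC,
    n_out: int = DEFAULT_N_OUT,
) -> Contour:
    """Circular moving-average smoothing + uniform arc-length resampling.

    The window is ``max(3, round(window_frac * n))`` vertices, forced odd,
    applied circularly so the base/apex regions are not edge artifacts;
    ``window_frac = 0`` skips smoothing and only resamples.  The output has
    exactly ``n_out`` vertices at (near-)equal arc-length spacing.
    """
    if not (0.0 <= window_frac <= 0.05):
        raise ValueError("window_frac must be in [0, 0.05]")
    if n_out < 64:
        raise ValueError("n_out must be >= 64")
    v = contour.vertices
    if window_frac > 0:
        w = max(3, int(round(window_frac * len(v))))
        if w % 2 == 0:
            w += 1
        kernel = np.ones(w) / w
        pad = w // 2
        ext = np.vstack([v[-pad:], v, v[:pad]])
        sm = np.column_stack(
            [np.convolve(ext[:, k], kernel, mode="valid") for k in (0, 1)]
        )
    else:
        sm = v
    out = _resample_closed(sm, n_out)
    if len(np.unique(np.round(out, 12), axis=0)) < 3:
        raise DegenerateObjectError("smoothing collapsed the contour")
    return replace(contour, vertices=out)


def _resample_closed(v: np.ndarray, n_out: int) -> np.ndarray:
    closed = np.vstack([v, v[:1]])
    seg = np.hypot(*np.diff(closed, axis=0).T)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total == 0:
        raise DegenerateObjectError("zero-length contour")
    t = np.linspace(0.0, total, n_out, endpoint=False)
    x = np.interp(t, s, closed[:, 0])
    y = np.interp(t, s, closed[:, 1])
    return np.column_stack([x, y])


# ---------------------------------------------------------------------------
# calibration / orientation


def calibrate(contour: Contour, pixels_per_cm: float) -> Contour:
    """Convert pixel coordinates to cm by dividing by ``pixels_per_cm``."""
    if not pixels_per_cm > 0:
        raise InvalidCalibrationError(f"pixels_per_cm must be > 0, got {pixels_per_cm}")
    return replace(
        contour,
        vertices=contour.vertices / pixels_per_cm,
        pixels_per_cm=contour.pixels_per_cm * pixels_per_cm,
        calibrated=True,
    )


def normalize_orientation(contour: Contour, mode: str = "principal-axis") -> Contour:
    """Rotate the contour so its major principal axis is vertical, wide end up.

    ``mode="as-imaged"`` trusts the photographing convention (organ placed
    base-up) and returns the contour unchanged.  ``mode="principal-axis"``
    rotates about the centroid so the major axis of the vertex set is
    vertical, picking of the two rotations the one that puts the wider end
    at the top (the base).  Nearly isotropic shapes (axis ratio < 1.05) are
    left as imaged with a warning — there is no meaningful axis to align.
    """
    if mode == "as-imaged":
        return contour
    if mode != "principal-axis":
        raise ValueError(f"unknown orientation mode {mode!r}")
    v = contour.vertices
    c = v.mean(axis=0)
    cov = np.cov((v - c).T)
    evals, evecs = np.linalg.eigh(cov)  # ascending
    ratio = np.sqrt(evals[1] / max(evals[0], 1e-300))
    if ratio < 1.05:
        warnings.warn("shape nearly isotropic; keeping as-imaged orientation", stacklevel=2)
        return replace(contour, orientation="normalized")
    major = evecs[:, 1]
    # rotate 'major' onto +y (downwards in the image frame)
    angle = np.arctan2(major[0], major[1])  # angle from +y axis
    rot = _rotation(angle)
    vv = (v - c) @ rot.T + c
    if _wider_end_is_down(vv):
        vv = (vv - c) @ _rotation(np.pi).T + c
    out = Contour(vv, pixels_per_cm=contour.pixels_per_cm,
                  orientation="normalized", calibrated=contour.calibrated)
    return out


def flip_vertical(contour: Contour) -> Contour:
    """Rotate 180 deg about the centroid (swap which end is up).

    Needed for leaves: principal-axis normalization puts the wider end (the
    blade) up, while leaf analysis wants the petiole end at the top.
    """
    v = contour.vertices
    c = v.mean(axis=0)
    return replace(contour, vertices=(v - c) @ _rotation(np.pi).T + c)


def _rotation(angle: float) -> np.ndarray:
    ca, sa = np.cos(angle), np.sin(angle)
    return np.array([[ca, -sa], [sa, ca]])


def _wider_end_is_down(v: np.ndarray, n_bins: int = 40) -> bool:
    """Compare horizontal extent of the top vs bottom thirds of the shape."""
    y0, y1 = v[:, 1].min(), v[:, 1].max()
    edges = np.linspace(y0, y1, n_bins + 1)
    idx = np.clip(np.digitize(v[:, 1], edges) - 1, 0, n_bins - 1)
    widths = np.zeros(n_bins)
    for b in range(n_bins):
        xs = v[idx == b, 0]
        if len(xs) >= 2:
            widths[b] = xs.max() - xs.min()
    third = n_bins // 3
    return widths[-third:].max() > widths[:third].max()
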