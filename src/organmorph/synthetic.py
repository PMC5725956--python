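"""Synthetic single-organ silhouettes with analytic ground truth.

Real cultivar image collections are rarely redistributable, so validation
runs on generated silhouettes that emulate what the imaging protocol
produces: one organ, uniform strongly coloured background, known
pixels-per-cm scale.  Four families cover the pipeline's feature space:

* ellipse "fruits" (plain prolate outlines),
* nippled fruits (ellipse + Gaussian radial bump at the apex),
* grooved discs (sinusoidal radial profile, an endocarp cross-section),
* leaves (ellipse blade + rectangular petiole).

Every fixture carries a ``truth`` map of descriptor values computed from
the generative parameters by closed form or high-resolution quadrature —
never by the measurement pipeline itself — so tests compare an independent
analytic oracle against the pipeline.

Geometry convention matches the pipeline: y grows downwards, organs are
generated base-up (apex at maximum y).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from PIL import Image
from scipy.integrate import quad
from scipy.special import ellipe
from skimage.draw import polygon2mask

from .errors import ResolutionTooLowError
from .segmentation import HSBRange

__all__ = [
    "Fixture",
    "make_ellipse_fruit",
    "make_nippled_fruit",
    "make_grooved_disc",
    "make_leaf",
    "make_blob",
    "generate_corpus",
    "BACKGROUND_RGB",
    "FOREGROUND_RGB",
    "BACKGROUND_HSB",
]

#: light-blue paperboard background / dark olive-green organ
BACKGROUND_RGB = (173, 216, 230)
FOREGROUND_RGB = (85, 107, 47)
#: HSB box covering the light-blue background (use with invert=True)
BACKGROUND_HSB = HSBRange(hue_min=180.0, hue_max=220.0, sat_min=0.05, sat_max=0.6,
                          bright_min=0.5, bright_max=1.0)

_N_BOUNDARY = 4096  # analytic boundary vertices before rasterization
_MARGIN_CM = 0.3


@dataclass
class Fixture:
    """A rasterized silhouette plus its analytic ground truth."""

    image: np.ndarray  # (H, W, 3) uint8
    mask: np.ndarray  # (H, W) bool, ground-truth foreground
    truth: dict
    params: dict
    pixels_per_cm: float
    seed: int = 0
    boundary_cm: np.ndarray = field(default=None, repr=False)  # analytic outline

    @property
    def hsb_background(self) -> HSBRange:
        return BACKGROUND_HSB

    def save(self, stem) -> None:
        """Write <stem>.png and a <stem>.json truth sidecar."""
        Image.fromarray(self.image).save(f"{stem}.png")
        meta = {"truth": self.truth, "params": self.params,
                "pixels_per_cm": self.pixels_per_cm, "seed": self.seed}
        with open(f"{stem}.json", "w") as fh:
            json.dump(meta, fh, indent=1, default=float)


def _rasterize(boundary_cm: np.ndarray, pixels_per_cm: float, seed: int,
               params: dict, truth: dict) -> Fixture:
    """Scan-fill an analytic boundary into an exact (non-antialiased) mask."""
    x, y = boundary_cm[:, 0], boundary_cm[:, 1]
    ox, oy = x.min() - _MARGIN_CM, y.min() - _MARGIN_CM
    w_cm = (x.max() - x.min()) + 2 * _MARGIN_CM
    h_cm = (y.max() - y.min()) + 2 * _MARGIN_CM
    W = int(np.ceil(w_cm * pixels_per_cm))
    H = int(np.ceil(h_cm * pixels_per_cm))
    rows = (y - oy) * pixels_per_cm
    cols = (x - ox) * pixels_per_cm
    extent_px = min(rows.max() - rows.min(), cols.max() - cols.min())
    if extent_px < 50:
        raise ResolutionTooLowError(
            f"object spans only {extent_px:.0f} px; raise pixels_per_cm"
        )
    mask = polygon2mask((H, W), np.column_stack([rows, cols]))
    image = np.empty((H, W, 3), dtype=np.uint8)
    image[:] = BACKGROUND_RGB
    image[mask] = FOREGROUND_RGB
    return Fixture(image=image, mask=mask, truth=truth, params=params,
                   pixels_per_cm=pixels_per_cm, seed=seed, boundary_cm=boundary_cm)


def _ellipse_perimeter(a: float, b: float) -> float:
    """Exact ellipse perimeter via the complete elliptic integral E."""
    a, b = max(a, b), min(a, b)
    e2 = 1.0 - (b / a) ** 2
    return float(4.0 * a * ellipe(e2))


def _polar_boundary(r_of_theta, n: int = _N_BOUNDARY) -> np.ndarray:
    """Closed boundary (x, y), y-down, from a polar radius function.

    theta = pi/2 points towards +y (the apex in the image frame).
    """
    theta = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    r = r_of_theta(theta)
    return np.column_stack([r * np.cos(theta), r * np.sin(theta)])


def _polar_area(r_of_theta) -> float:
    val, _ = quad(lambda t: 0.5 * r_of_theta(np.array([t]))[0] ** 2, 0.0,
                  2.0 * np.pi, limit=400)
    return float(val)


def _polar_arclength(r_of_theta, eps: float = 1e-6) -> float:
    def ds(t):
        r = r_of_theta(np.array([t]))[0]
        rp = (r_of_theta(np.array([t + eps]))[0] - r_of_theta(np.array([t - eps]))[0]) / (2 * eps)
        return np.sqrt(r * r + rp * rp)
    val, _ = quad(ds, 0.0, 2.0 * np.pi, limit=400)
    return float(val)


# ---------------------------------------------------------------------------
# fixture families


def make_ellipse_fruit(a: float, b: float, rotation: float = 0.0,
                       pixels_per_cm: float = 200.0, seed: int = 0) -> Fixture:
    """Ellipse silhouette: vertical semi-axis ``a`` >= horizontal ``b`` (cm).

    Truth (after orientation normalization): area = pi*a*b, height = 2a,
    max_tr_diam = 2b, sh_idx = a/b, both symmetries 0.5, circ from the exact
    elliptic-integral perimeter, area convexity 1.
    """
    if not (a >= b > 0):
        raise ValueError("require a >= b > 0")
    theta = np.linspace(0.0, 2.0 * np.pi, _N_BOUNDARY, endpoint=False)
    xy = np.column_stack([b * np.cos(theta), a * np.sin(theta)])
    if rotation:
        phi = np.deg2rad(rotation)
        rot = np.array([[np.cos(phi), -np.sin(phi)], [np.sin(phi), np.cos(phi)]])
        xy = xy @ rot.T
    P = _ellipse_perimeter(a, b)
    truth = {
        "area": np.pi * a * b,
        "perimeter": P,
        "height": 2 * a,
        "max_tr_diam": 2 * b,
        "sh_idx": a / b,
        "ver_sym": 0.5,
        "tr_sym": 0.5,
        "circ": 4 * np.pi * (np.pi * a * b) / P**2,
        "st_ar_conv": 1.0,
        "ellipse_major": 2 * a,
        "ellipse_minor": 2 * b,
        "apex_curvature": a / b**2,  # curvature at the major-axis tip
        "nipple_present": 0.0,
        "nipple_height": 0.0,
    }
    params = {"kind": "ellipse", "a": a, "b": b, "rotation": rotation}
    return _rasterize(xy, pixels_per_cm, seed, params, truth)


def make_nippled_fruit(a: float, b: float, bump_height: float,
                       bump_sigma: float = 0.15, pixels_per_cm: float = 200.0,
                       seed: int = 0) -> Fixture:
    """Ellipse plus a Gaussian radial bump centred at the apex angle.

    The bump adds ``bump_height * exp(-d^2 / (2 sigma_theta^2))`` to the
    polar radius, with sigma_theta chosen so the bump's arc-length width at
    the apex is ``bump_sigma`` cm; the apex therefore protrudes by exactly
    ``bump_height``.  ``bump_height = 0`` reduces to the plain ellipse.
    """
    if bump_height < 0:
        raise ValueError("bump_height must be >= 0")
    sigma_theta = bump_sigma / a  # arc length ~ r*dtheta with r(apex)=a

    def r_of_theta(theta):
        r_e = a * b / np.sqrt((b * np.sin(theta)) ** 2 + (a * np.cos(theta)) ** 2)
        # NB ellipse here has major axis along theta=pi/2 (towards +y)
        d = np.arctan2(np.sin(theta - np.pi / 2), np.cos(theta - np.pi / 2))
        return r_e + bump_height * np.exp(-(d**2) / (2 * sigma_theta**2))

    # polar form of the ellipse with semi-major axis along +/- y:
    # r(theta) = ab / sqrt(b^2 sin^2 + a^2 cos^2) ... checked: theta=pi/2 -> a
    xy = _polar_boundary(r_of_theta)
    area = _polar_area(r_of_theta)
    truth = {
        "area": area,
        "height": 2 * a + bump_height if bump_height > 0 else 2 * a,
        "nipple_present": 1.0 if bump_height > 0 else 0.0,
        "nipple_height": bump_height,
        "max_tr_diam": 2 * b,
    }
    params = {"kind": "nippled_fruit", "a": a, "b": b,
              "bump_height": bump_height, "bump_sigma": bump_sigma}
    return _rasterize(xy, pixels_per_cm, seed, params, truth)


def make_grooved_disc(R: float, amp: float, n_grooves: int = 8,
                      pixels_per_cm: float = 200.0, seed: int = 0) -> Fixture:
    """Disc with sinusoidal grooves: r(theta) = R + amp*sin(n_grooves*theta).

    Emulates an endocarp cross-section viewed end-on.  Truth: area =
    pi(R^2 + amp^2/2), centroid distances R -+ amp, minimum bounding circle
    diameter 2(R + amp), hull/convexity values by dense numeric oracle.
    """
    if not (0 <= amp < R):
        raise ValueError("require 0 <= amp < R")
    if amp > 0 and n_grooves < 3:
        raise ValueError("n_grooves must be >= 3")

    def r_of_theta(theta):
        return R + amp * np.sin(n_grooves * theta)

    xy = _polar_boundary(r_of_theta)
    truth = {
        "area": np.pi * (R**2 + amp**2 / 2.0),
        "min_cent_cnt": R - amp,
        "max_cent_cnt": R + amp,
        "diam_min_bd_cir": 2 * (R + amp),
        "diam_inscr_cir": 2 * (R - amp) if amp > 0 else 2 * R,
        "st_ar_conv": _convexity_oracle(r_of_theta) if amp > 0 else 1.0,
    }
    params = {"kind": "grooved_disc", "R": R, "amp": amp, "n_grooves": n_grooves}
    return _rasterize(xy, pixels_per_cm, seed, params, truth)


def _convexity_oracle(r_of_theta, n: int = 100_000) -> float:
    """Area / convex-hull-area by dense sampling, independent of the pipeline."""
    from scipy.spatial import ConvexHull

    theta = np.linspace(0, 2 * np.pi, n, endpoint=False)
    r = r_of_theta(theta)
    pts = np.column_stack([r * np.cos(theta), r * np.sin(theta)])
    w = np.roll(pts, -1, axis=0)
    area = abs((pts[:, 0] * w[:, 1] - w[:, 0] * pts[:, 1]).sum() / 2)
    return float(area / ConvexHull(pts).volume)


def make_leaf(blade_a: float, blade_b: float, petiole_len: float,
              petiole_w: float, pixels_per_cm: float = 200.0,
              seed: int = 0) -> Fixture:
    """Ellipse blade with a rectangular petiole attached at the base (top).

    The petiole must be narrower than the default split threshold
    (petiole_w < 0.15 * blade width).  Truth: petiole_hgt = petiole_len,
    petiole_area = petiole_len * petiole_w, blade truths from the ellipse.
    """
    if petiole_len > 0 and not petiole_w < 0.15 * 2 * blade_b:
        raise ValueError("petiole too wide for the default split threshold")
    from shapely.geometry import Polygon, box
    from shapely.ops import unary_union

    theta = np.linspace(0, 2 * np.pi, _N_BOUNDARY, endpoint=False)
    ell = Polygon(np.column_stack([blade_b * np.cos(theta), blade_a * np.sin(theta)]))
    if petiole_len > 0:
        # base (petiole end) at minimum y: rectangle on top of the ellipse,
        # overlapping 2% of blade_a so the union is a single polygon
        rect = box(-petiole_w / 2, -blade_a - petiole_len, petiole_w / 2,
                   -blade_a + 0.02 * blade_a)
        shape = unary_union([ell, rect])
    else:
        shape = ell
    xy = np.asarray(shape.exterior.coords)[:-1]
    blade_P = _ellipse_perimeter(blade_a, blade_b)
    truth = {
        "petiole_hgt": petiole_len,
        "petiole_area": petiole_len * petiole_w,
        "blade_area": np.pi * blade_a * blade_b,
        "blade_hgt": 2 * blade_a,
        "max_tr_diam": 2 * blade_b,
        "height": 2 * blade_a + petiole_len,
        "sh_idx": blade_a / blade_b,
        "blade_circ": 4 * np.pi * (np.pi * blade_a * blade_b) / blade_P**2,
        "tip_curvature": blade_a / blade_b**2,
    }
    params = {"kind": "leaf", "blade_a": blade_a, "blade_b": blade_b,
              "petiole_len": petiole_len, "petiole_w": petiole_w}
    return _rasterize(xy, pixels_per_cm, seed, params, truth)


def make_blob(mean_radius: float = 1.0, roughness: float = 0.1,
              n_modes: int = 6, pixels_per_cm: float = 200.0,
              seed: int = 0) -> Fixture:
    """Random smooth star-shaped blob (Fourier radial perturbation).

    No closed-form truths beyond area by quadrature; used for property
    tests (isoperimetric bound, oracle cross-checks) where only internal
    consistency matters.
    """
    rng = np.random.default_rng(seed)
    amps = roughness * mean_radius * rng.uniform(0.2, 1.0, n_modes) / np.arange(1, n_modes + 1)
    phases = rng.uniform(0, 2 * np.pi, n_modes)
    ks = np.arange(2, n_modes + 2)

    def r_of_theta(theta):
        r = np.full_like(theta, mean_radius, dtype=float)
        for A, ph, k in zip(amps, phases, ks):
            r = r + A * np.sin(k * theta + ph)
        return r

    xy = _polar_boundary(r_of_theta)
    truth = {"area": _polar_area(r_of_theta),
             "perimeter": _polar_arclength(r_of_theta)}
    params = {"kind": "blob", "mean_radius": mean_radius,
              "roughness": roughness, "n_modes": n_modes}
    return _rasterize(xy, pixels_per_cm, seed, params, truth)


# ---------------------------------------------------------------------------
# corpus generation (batch-pipeline fixtures)


def generate_corpus(outdir, n_per_group: int = 10, pixels_per_cm: float = 150.0,
                    seed: int = 0) -> list:
    """Materialize a deterministic 3-cultivar fruit corpus on disk.

    Three synthetic "cultivars" with distinct shape-index and nipple
    phenotypes; per-specimen size jitter is seeded.  Each specimen gets an
    A-position and a B-position image named ``<group>_<nn>_<A|B>.png``.
    Returns the list of written stems.
    """
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    groups = {
        "roundcv": {"a": 1.15, "b": 1.0, "bump": 0.0},
        "oblongcv": {"a": 1.8, "b": 1.0, "bump": 0.0},
        "nippledcv": {"a": 1.5, "b": 1.0, "bump": 0.3},
    }
    rng = np.random.default_rng(seed)
    stems = []
    for gname, g in groups.items():
        for i in range(n_per_group):
            scale = 1.0 + 0.08 * rng.standard_normal()
            a, b = g["a"] * scale, g["b"] * scale
            for pos in ("A", "B"):
                if g["bump"] > 0:
                    fx = make_nippled_fruit(a, b, g["bump"] * scale,
                                            pixels_per_cm=pixels_per_cm, seed=seed)
                else:
                    fx = make_ellipse_fruit(a, b, pixels_per_cm=pixels_per_cm,
                                            seed=seed)
                stem = outdir / f"{gname}_{i:02d}_{pos}"
                fx.save(stem)
                stems.append(str(stem))
    return stems
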