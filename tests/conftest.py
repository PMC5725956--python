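"""Shared fixtures: analytic contours and the image->contour measurement path."""

import warnings

import numpy as np
import pytest

import organmorph as om
from organmorph.contour import Contour, flip_vertical
from organmorph.segmentation import clean_mask, threshold_hsb


def ellipse_contour(a: float, b: float, n: int = 1000, uniform: bool = True) -> Contour:
    """Analytic vertical ellipse (semi-axes a vertical, b horizontal), cm."""
    t = np.linspace(0.0, 2.0 * np.pi, max(n, 64) * 4, endpoint=False)
    c = Contour(np.column_stack([b * np.cos(t), a * np.sin(t)]), calibrated=True)
    if uniform:
        c = om.smooth_resample(c, window_frac=0.0, n_out=n)
    return c


def circle_contour(r: float, n: int = 1000) -> Contour:
    return ellipse_contour(r, r, n)


def egg_contour(h_apex: float, h_base: float, b: float, n: int = 1000) -> Contour:
    """Two half-ellipses sharing the widest chord (width 2b) at y = 0.

    Apex (max y) at +h_apex, base at -h_base; the widest chord sits at a
    height fraction h_apex / (h_apex + h_base) from the apex.
    """
    t = np.linspace(0.0, 2.0 * np.pi, 4000, endpoint=False)
    y = np.where(np.sin(t) >= 0, h_apex * np.sin(t), h_base * np.sin(t))
    c = Contour(np.column_stack([b * np.cos(t), y]), calibrated=True)
    return om.smooth_resample(c, window_frac=0.0, n_out=n)


def measure_fixture(fx, window_frac=0.01, n_out=1000, orient=True, leaf=False):
    """The full image->contour path on a synthetic fixture."""
    mask = clean_mask(threshold_hsb(fx.image, fx.hsb_background, invert=True))
    c = om.trace_boundary(mask)
    c = om.smooth_resample(c, window_frac, n_out)
    c = om.calibrate(c, fx.pixels_per_cm)
    if orient:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            c = om.normalize_orientation(c, "principal-axis")
        if leaf:
            c = flip_vertical(c)
    return c


@pytest.fixture(scope="session")
def disc_fixture():
    from organmorph.synthetic import make_ellipse_fruit

    return make_ellipse_fruit(1.0, 1.0, pixels_per_cm=200.0)


@pytest.fixture(scope="session")
def prolate_fixture():
    from organmorph.synthetic import make_ellipse_fruit

    return make_ellipse_fruit(2.0, 1.0, pixels_per_cm=200.0)
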