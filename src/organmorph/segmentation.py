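"""Colour-threshold segmentation of single-organ photographs.

The imaging protocol photographs one organ on a uniform, strongly coloured
background (light-blue paperboard works well for green/black olives), so a
hue/saturation/brightness box either selects the background (``invert=True``)
or the organ directly.  The result is cleaned into exactly one solid
8-connected object, the precondition for boundary tracing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import measure
from skimage.color import rgb2hsv

from .errors import (
    NoObjectError,
    ObjectClippedError,
    UnsupportedImageError,
)

__all__ = ["HSBRange", "threshold_hsb", "clean_mask", "is_binary_image", "mask_from_binary_image"]


@dataclass(frozen=True)
class HSBRange:
    """A box in hue/saturation/brightness space.

    Hue is in degrees [0, 360) and may wrap: ``hue_min > hue_max`` selects the
    interval crossing 0 deg (useful for red backgrounds).  Saturation and
    brightness are fractions in [0, 1].
    """

    hue_min: float
    hue_max: float
    sat_min: float = 0.0
    sat_max: float = 1.0
    bright_min: float = 0.0
    bright_max: float = 1.0

    def __post_init__(self) -> None:
        for lo, hi, name in (
            (self.sat_min, self.sat_max, "saturation"),
            (self.bright_min, self.bright_max, "brightness"),
        ):
            if not (0.0 <= lo <= hi <= 1.0):
                raise ValueError(f"invalid {name} interval [{lo}, {hi}]")
        if not (0.0 <= self.hue_min < 360.0 and 0.0 <= self.hue_max < 360.0):
            raise ValueError("hue bounds must lie in [0, 360)")

    def contains_hue(self, hue_deg: np.ndarray) -> np.ndarray:
        if self.hue_min <= self.hue_max:
            return (hue_deg >= self.hue_min) & (hue_deg <= self.hue_max)
        # wrapped interval crossing 0 degrees
        return (hue_deg >= self.hue_min) | (hue_deg <= self.hue_max)


def threshold_hsb(image: np.ndarray, hsb: HSBRange, invert: bool = False) -> np.ndarray:
    """Binarize an RGB image by an HSB box; pixelwise, no cleaning.

    A pixel is foreground iff its HSB triple lies inside all three intervals,
    XOR ``invert`` (``invert=True`` selects the complement — the usual mode
    when the box describes the *background* colour).

    Returns a 2-D boolean mask.  An empty selection returns an all-background
    mask with a warning rather than raising.
    """
    if image.ndim != 3 or image.shape[2] != 3:
        raise UnsupportedImageError(
            f"expected a 3-channel RGB image, got shape {image.shape}"
        )
    hsv = rgb2hsv(image)
    hue = hsv[..., 0] * 360.0
    sel = (
        hsb.contains_hue(hue)
        & (hsv[..., 1] >= hsb.sat_min)
        & (hsv[..., 1] <= hsb.sat_max)
        & (hsv[..., 2] >= hsb.bright_min)
        & (hsv[..., 2] <= hsb.bright_max)
    )
    mask = sel ^ invert
    if not mask.any():
        warnings.warn("HSB threshold selected no foreground pixels", stacklevel=2)
    return mask


def clean_mask(mask: np.ndarray) -> np.ndarray:
    """Keep the largest 8-connected component and fill its interior holes.

    Replaces the manual touch-up step of interactive thresholding with a
    deterministic policy.  Idempotent.  Raises :class:`NoObjectError` on an
    empty mask and :class:`ObjectClippedError` if the surviving object
    touches the image border (its silhouette would be truncated).
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise NoObjectError("mask contains no foreground pixels")
    labels = measure.label(mask, connectivity=2)
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    keep = counts.argmax()
    obj = labels == keep
    obj = ndimage.binary_fill_holes(obj)
    border = (
        obj[0, :].any() or obj[-1, :].any() or obj[:, 0].any() or obj[:, -1].any()
    )
    if border:
        raise ObjectClippedError("object touches the image border")
    return obj


def is_binary_image(image: np.ndarray) -> bool:
    """True if the raster is a pre-made black/white mask.

    Requires at most two distinct values, both achromatic (R = G = B), so a
    two-colour photograph of an organ on a coloured background still takes
    the HSB-threshold path.
    """
    if image.ndim == 3:
        flat = image.reshape(-1, image.shape[2])
        if not (flat == flat[:, :1]).all():
            return False
        flat = flat[:, 0]
    else:
        flat = image.ravel()
    return len(np.unique(flat)) <= 2


def mask_from_binary_image(image: np.ndarray) -> np.ndarray:
    """Accept a pre-binarized image directly as a mask (white = object)."""
    if image.ndim == 3:
        gray = image.mean(axis=2)
    else:
        gray = np.asarray(image, dtype=float)
    return gray > gray.min() if gray.max() > gray.min() else gray > -np.inf
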