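"""Exception hierarchy for organmorph.

Every recoverable failure mode in the pipeline raises a subclass of
:class:`OrganMorphError`, so batch drivers can catch one type and log the
offending image instead of aborting the run.
"""


class OrganMorphError(Exception):
    """Base class for all organmorph errors."""


class UnsupportedImageError(OrganMorphError):
    """Input raster is not a 3-channel 8-bit colour image."""


class NoObjectError(OrganMorphError):
    """A mask contains no foreground pixels."""


class ObjectClippedError(OrganMorphError):
    """The organ touches the image border; measurements would be truncated."""


class InvalidMaskError(OrganMorphError):
    """Mask violates the single-object / no-holes invariants."""


class DegenerateObjectError(OrganMorphError):
    """Object too small or thin to yield a valid closed contour (< 3 points)."""


class InvalidCalibrationError(OrganMorphError):
    """Non-positive pixels-per-cm factor."""


class ArcTooShortError(OrganMorphError):
    """Curvature requested on an arc with fewer than 7 vertices."""


class ResolutionTooLowError(OrganMorphError):
    """Synthetic fixture rasterized below the minimum usable resolution."""


class InsufficientReplicatesError(OrganMorphError):
    """A statistics group has fewer than 2 values."""


class DegenerateDataError(OrganMorphError):
    """ANOVA on constant, identical groups: F is undefined."""


class EmptyGroupError(OrganMorphError):
    """A declared group produced zero trait rows in a batch run."""
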