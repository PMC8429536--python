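"""Exception hierarchy for the noise-measurement pipeline.

Boundary overflow of a measurement shape is deliberately a *different*
condition from the trachea-containment exclusion rule: the former is an
error (the shape left the image grid), the latter is ordinary bookkeeping
(the shape left the segmented lumen) and is recorded, not raised.
"""


class CTNoiseError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(CTNoiseError, ValueError):
    """A parameter violates its contract (e.g. non-positive area)."""


class BoundaryError(CTNoiseError):
    """A measurement shape or jitter offset extends past the image grid."""


class VolumeReadError(CTNoiseError):
    """An image file could not be read into a calibrated HU volume."""


class SeedPointError(CTNoiseError):
    """The segmentation seed does not lie in air."""


class NoBifurcationError(CTNoiseError):
    """No axial 2-components-to-1 transition found in the airway mask."""


class PlacementError(CTNoiseError):
    """A measurement isocenter cannot be placed at the requested height."""


class ScanFailureError(CTNoiseError):
    """No measurement height could be placed for a scan."""


class UndefinedStatisticError(CTNoiseError, ValueError):
    """A statistic is undefined for the given input (e.g. SD of < 2 values)."""


class PhantomSpecError(CTNoiseError, ValueError):
    """A phantom specification is geometrically or numerically invalid."""


class SegmentationLeakWarning(UserWarning):
    """The grown airway region touches all six crop faces (possible leak)."""
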