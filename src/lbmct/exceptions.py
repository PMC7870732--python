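"""Exception hierarchy for lbmct.

All errors derive from :class:`LbmctError` so callers can catch the whole
family; each subclass maps to one failure mode named in the public API
contracts (bad file, bad geometry, bad value, degenerate statistics).
"""


class LbmctError(Exception):
    """Base class for all lbmct errors."""


class FormatError(LbmctError, ValueError):
    """A file or DICOM series violates the expected on-disk format."""


class BoundsError(LbmctError, IndexError):
    """A slice range or index is outside the volume."""


class DimensionError(LbmctError, ValueError):
    """Array shapes that must agree do not."""


class DomainError(LbmctError, ValueError):
    """A scalar input is outside the physically meaningful domain."""


class GeometryError(LbmctError, ValueError):
    """A spherical ROI or kernel does not fit inside the volume."""


class ContentError(LbmctError, ValueError):
    """The voxel content cannot support the requested operation (e.g. empty mask)."""


class SegmentationError(LbmctError, RuntimeError):
    """Adaptive lesion segmentation produced an empty mask."""


class FitError(LbmctError, ValueError):
    """Regression input is degenerate (too few points, zero variance)."""


class DegenerateInputError(LbmctError, ValueError):
    """Paired statistics requested on zero-variance differences."""


class SpecError(LbmctError, ValueError):
    """A synthetic-data specification is internally inconsistent."""


class ConfigError(LbmctError, ValueError):
    """Required configuration (e.g. blood-pool stats) is missing."""
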