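"""Exception hierarchy.

All domain errors derive from :class:`ContourMetricsError` so callers can
catch the package's failures without masking programming errors.
"""


class ContourMetricsError(Exception):
    """Base class for all errors raised by contourmetrics."""


class GeometryError(ContourMetricsError):
    """Two masks are not comparable (different lattice dimensions or spacing)."""


class DimensionalityError(ContourMetricsError):
    """A volume is not a 3D scalar image."""


class MetadataError(ContourMetricsError):
    """Header metadata is invalid (e.g. non-positive voxel spacing)."""


class EmptySurfaceError(ContourMetricsError):
    """A surface metric was requested for a mask with no foreground voxels."""


class ManifestError(ContourMetricsError):
    """A case manifest or case table is malformed."""


class DegenerateInputError(ContourMetricsError):
    """A statistical routine received input on which its result is undefined
    (constant vector, empty group, too few observations)."""


class GenerationError(ContourMetricsError):
    """The synthetic generator could not satisfy a perturbation spec."""
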