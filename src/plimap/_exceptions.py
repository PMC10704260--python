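"""Exception hierarchy shared across the package."""


class PlimapError(Exception):
    """Base class for all package-specific errors."""


class InvalidArgumentError(PlimapError, ValueError):
    """An argument violates a documented precondition."""


class DecompositionError(PlimapError):
    """Polar decomposition failed (singular or grossly non-physical matrix)."""


class InvalidRetarderError(PlimapError):
    """A matrix presented as a retarder factor is not one (3x3 block not orthogonal)."""


class InsufficientDataError(PlimapError):
    """Too few valid samples for the requested statistic or fit."""


class BranchRequiredError(PlimapError):
    """Phase-unwrap correction requested without a resolved branch."""


class AlreadyCorrectedError(PlimapError):
    """Phase-unwrap correction applied to data that already carries the corrected flag."""


class OutOfBoundsError(PlimapError):
    """A geometric primitive (path, centerline) leaves the image frame."""


class EmptyROIError(PlimapError):
    """An ROI mask selects no valid pixels."""


class DegenerateGeometryError(PlimapError):
    """Point set admits no finite circle (collinear or coincident points)."""


class ContainerError(PlimapError):
    """Stack container on disk violates the plane layout contract."""


class MetadataError(PlimapError):
    """Stack container is missing required metadata."""


class ConfigError(PlimapError):
    """Pipeline configuration is malformed; message names the offending field."""
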