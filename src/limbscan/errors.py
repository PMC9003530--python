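"""Exception hierarchy for the scanning pipeline.

Every stage raises a subclass of :class:`LimbscanError` so callers (and the
CLI) can distinguish pipeline failures from programming errors.  Errors that
signal a bad argument also derive from :class:`ValueError` so they behave
conventionally in library use.
"""


class LimbscanError(Exception):
    """Base class for all pipeline errors."""


class InvalidArgumentError(LimbscanError, ValueError):
    """An argument violates a documented precondition."""


class BehindCameraError(InvalidArgumentError):
    """A point with non-positive depth cannot be projected."""


class DegenerateConfigurationError(LimbscanError, ValueError):
    """A point configuration is too degenerate for rigid alignment."""


class IncompleteObservationError(LimbscanError, ValueError):
    """A camera is missing checkerboard corner observations."""


class EmptySegmentationError(LimbscanError, RuntimeError):
    """A segmentation stage produced an empty mask.

    Carries the name of the failing stage so an operator can intervene
    (e.g. supply a seed pixel for region selection).
    """

    def __init__(self, stage: str, message: str | None = None):
        self.stage = stage
        super().__init__(message or f"empty segmentation after stage '{stage}'")


class DegenerateInputError(LimbscanError, ValueError):
    """An input raster is constant where contrast is required."""


class NoOverlapError(LimbscanError, RuntimeError):
    """ICP found zero correspondences between two clouds."""


class InsufficientInputError(LimbscanError, ValueError):
    """Too few points for surface reconstruction."""


class NonManifoldError(LimbscanError, ValueError):
    """A mesh operation requires a manifold input."""


class UndefinedMetricError(LimbscanError, ValueError):
    """A metric is undefined for the given (empty) inputs."""


class OutOfRangeError(LimbscanError, ValueError):
    """A query (e.g. a section height) falls outside the object."""


class VisibilityError(LimbscanError, RuntimeError):
    """A calibration target corner falls behind a camera."""


class MissingInputError(LimbscanError, FileNotFoundError):
    """A pipeline stage is missing a required input artefact."""


class ConfigurationError(LimbscanError, ValueError):
    """The session configuration is inconsistent."""
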