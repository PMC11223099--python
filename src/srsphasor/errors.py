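"""Exception hierarchy.

Every error raised by this package derives from :class:`SRSPhasorError`, so
callers can catch one type at a pipeline boundary.  Subclasses also derive
from the closest builtin (ValueError/RuntimeError) so generic handling keeps
working.
"""


class SRSPhasorError(Exception):
    """Base class for all srsphasor errors."""


class InvalidParameterError(SRSPhasorError, ValueError):
    """A parameter is outside its documented domain (non-finite, wrong sign...)."""


class DegenerateAxisError(SRSPhasorError, ValueError):
    """A wavenumber axis would contain fewer than two channels."""


class DegenerateSpectrumError(SRSPhasorError, ValueError):
    """A spectrum has too few channels for the requested transform."""


class DegenerateReferenceError(SRSPhasorError, ValueError):
    """A phasor reference cloud collapses to a degenerate (zero-area) region."""


class AmbiguousReferenceError(SRSPhasorError, ValueError):
    """A phasor reference cloud is too spread out to define a class region."""


class PlacementError(SRSPhasorError, RuntimeError):
    """Phantom geometry could not be placed without overlap.

    Attributes
    ----------
    compartment : str
        Name of the object class that failed to place.
    """

    def __init__(self, compartment: str, message: str | None = None):
        self.compartment = compartment
        super().__init__(message or f"could not place {compartment!r} without overlap")


class FormatError(SRSPhasorError, ValueError):
    """A file on disk does not match the expected stack/sidecar layout."""


class DegenerateHistogramError(SRSPhasorError, ValueError):
    """Automatic thresholding on a constant (single-valued) image."""


class EmptySegmentError(SRSPhasorError, ValueError):
    """A requested segment label has no pixels."""


class AxisMismatchError(SRSPhasorError, ValueError):
    """A requested Raman shift is not present on the stack's wavenumber axis."""


class GeometryError(SRSPhasorError, ValueError):
    """Missing or inconsistent physical geometry (pixel size, z step)."""


class UndefinedCorrelationError(SRSPhasorError, ValueError):
    """Correlation requested on data with zero variance."""


class InsufficientDataError(SRSPhasorError, ValueError):
    """Too few observations/groups for the requested statistic."""


class SchemaError(SRSPhasorError, ValueError):
    """A tabular input is missing a required column."""


class ConfigError(SRSPhasorError, ValueError):
    """A run configuration failed validation."""


class StageError(SRSPhasorError, RuntimeError):
    """A pipeline stage failed.

    Attributes
    ----------
    stage : str
        Name of the failing stage.
    """

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {message}")
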