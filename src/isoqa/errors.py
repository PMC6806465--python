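"""Exception hierarchy for the QA pipeline.

Every stage raises a subclass of :class:`IsoQAError`, so the workflow layer
can isolate a failed stage into a structured report entry instead of
aborting the whole weekly analysis.
"""


class IsoQAError(Exception):
    """Base class for all package errors."""


class DomainError(IsoQAError, ValueError):
    """An input violates a documented domain restriction (e.g. angle range)."""


class GeometryError(IsoQAError, ValueError):
    """Geometrically impossible request (point behind source, field off imager)."""


class DetectionError(IsoQAError, RuntimeError):
    """A required image feature (BB, field edge) could not be found."""


class AmbiguityError(DetectionError):
    """Two equally good label assignments exist; no deterministic choice."""


class UnderdeterminedError(IsoQAError, ValueError):
    """Too few observations for the estimator (e.g. one ray for triangulation)."""


class ConditioningError(IsoQAError, ValueError):
    """Observation geometry is numerically degenerate (near-parallel rays)."""


class DegenerateConfigurationError(IsoQAError, ValueError):
    """Point configuration does not determine a rigid transform."""


class ConfigError(IsoQAError, ValueError):
    """Unknown template/config key or invalid configuration value."""


class ManifestError(IsoQAError, ValueError):
    """Session manifest incomplete or inconsistent with files on disk."""


class UndefinedTestError(IsoQAError, ValueError):
    """Statistical test undefined for the given data (e.g. all zero differences)."""


class XMLFormatError(IsoQAError, ValueError):
    """Acquisition-sequence document malformed or fails validation."""
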