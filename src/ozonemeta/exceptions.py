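"""Shared exception hierarchy.

Every contract violation raises a subclass of :class:`OzoneMetaError`, so
callers can catch one base type at pipeline level while tests assert the
specific failure mode.
"""


class OzoneMetaError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(OzoneMetaError, ValueError):
    """An input violates a type invariant or enum contract."""


class DegenerateSampleError(OzoneMetaError, ValueError):
    """Too few observations for the estimator's degrees of freedom."""


class ZeroDispersionError(OzoneMetaError, ZeroDivisionError):
    """A standardizer (pooled SD or change SD) is exactly zero."""


class EmptySetError(OzoneMetaError, ValueError):
    """An aggregation was asked for zero studies / zero elements."""


class UndefinedRatioError(OzoneMetaError, ZeroDivisionError):
    """A ratio (RR, odds, NNH) is undefined for the given inputs."""


class DegenerateNoiseError(OzoneMetaError, ValueError):
    """A noise ROI has zero standard deviation."""


class DegenerateTestError(OzoneMetaError, ValueError):
    """A paired test was requested on zero-variance differences."""


class ConfigurationError(OzoneMetaError, ValueError):
    """A run configuration is incomplete or inconsistent."""
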