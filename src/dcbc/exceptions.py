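"""Typed errors raised across the package.

Every failure mode a caller can reasonably recover from gets its own class;
all inherit from :class:`DCBCError` so scripts can catch the lot.
"""


class DCBCError(Exception):
    """Base class for all errors raised by this package."""


class ParameterError(DCBCError, ValueError):
    """An argument is out of its documented domain."""


class MeshError(DCBCError):
    """A surface mesh violates its structural invariants."""


class GeometryError(DCBCError):
    """An operation requiring spherical geometry received a non-sphere mesh."""


class MaskedVertexError(DCBCError):
    """A vertex-level query targeted a masked / invalid vertex."""


class EvaluationError(DCBCError):
    """A criterion cannot be computed on the given inputs (e.g. no usable bins)."""


class CalibrationError(DCBCError):
    """Smoothing calibration could not reach its target within the iteration cap."""


class FormatError(DCBCError):
    """A file could not be parsed into the expected structure."""
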