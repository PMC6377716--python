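"""Exception hierarchy for esovol.

Every domain failure raises a subclass of :class:`EsovolError`, so callers
(and the CLI) can distinguish domain errors from programming errors.
"""


class EsovolError(Exception):
    """Base class for all esovol domain errors."""


class MetadataError(EsovolError):
    """An image file is readable but lacks, or has invalid, required header
    metadata (e.g. a non-positive slice spacing)."""


class ParameterError(EsovolError):
    """A user-supplied parameter is outside its valid domain."""


class GeometryError(EsovolError):
    """A geometric precondition failed: contour outside the grid, slice index
    out of range, mask/volume shape mismatch."""


class ValidationError(EsovolError):
    """A domain object violates its structural invariants."""


class DegenerateInputError(EsovolError):
    """An input collapsed to something the algorithm cannot operate on,
    e.g. a contour that rasterizes to zero pixels between key slices."""


class UndefinedStatisticError(EsovolError):
    """A statistic is mathematically undefined for the given data
    (zero total variance, |r| = 1 in the Fisher transform, ...)."""


class SampleSizeError(EsovolError):
    """Too few observations for the requested statistic."""


class FixtureIntegrityError(EsovolError):
    """A packaged data fixture failed its integrity gate."""
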