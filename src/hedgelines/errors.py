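"""Exception hierarchy for the hedgelines pipeline.

Every stage raises a subclass of :class:`HedgelinesError` so callers can
distinguish data problems (alignment, coverage, missing squares) from
programming errors.
"""


class HedgelinesError(Exception):
    """Base class for all hedgelines errors."""


class AlignmentError(HedgelinesError):
    """Two grids that must share georeferencing do not (names the field)."""


class ConfigurationError(HedgelinesError):
    """A configuration value is inconsistent with the supplied data."""


class ParameterError(HedgelinesError, ValueError):
    """A numeric parameter is outside its documented range."""


class GeometryError(HedgelinesError):
    """An input geometry is invalid (reports the offending index)."""


class CoverageError(HedgelinesError):
    """A geometry falls outside the extent of the raster it is sampled from."""


class StateError(HedgelinesError):
    """An operation was called before its prerequisites (e.g. attribution)."""


class SquareLookupError(HedgelinesError, KeyError):
    """A requested 1-km square id is unknown."""


class CompletenessError(HedgelinesError):
    """Sampled squares required by the stratum table are missing (lists ids)."""


class UndefinedStatisticError(HedgelinesError, ZeroDivisionError):
    """A statistic was requested from an empty confusion matrix or row."""
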