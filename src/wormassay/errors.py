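"""Exception hierarchy for wormassay.

All errors raised by the package derive from :class:`WormAssayError` so
callers can catch the package's failures with one clause.
"""


class WormAssayError(Exception):
    """Base class for all wormassay errors."""


class FormatError(WormAssayError):
    """A file could not be mapped onto the expected columns/fields."""


class DataError(WormAssayError):
    """A file parsed, but its content violates a data invariant."""


class ParameterError(WormAssayError):
    """A parameter value is outside its admissible range."""


class ConfigError(WormAssayError):
    """A configuration file or analysis design spec is invalid."""


class InsufficientDataError(WormAssayError):
    """Too few (valid) observations to compute the requested quantity."""


class UndefinedIndexError(WormAssayError):
    """A ratio index is undefined (zero denominator); the animal is
    flagged rather than silently dropped."""
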