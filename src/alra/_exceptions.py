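"""Exception hierarchy.

Every error raised on purpose by this package derives from :class:`AlraError`,
so callers can catch one type at the pipeline boundary.
"""


class AlraError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(AlraError):
    """A file is missing, or is not in the declared on-disk format."""


class ConsistencyError(AlraError):
    """Components of a multi-file input disagree (e.g. sidecar lengths vs. matrix dims)."""


class ValidationError(AlraError):
    """An in-memory matrix violates a structural invariant (negative entries, ...)."""


class EmptyResultError(AlraError):
    """A filter removed every cell or every gene."""


class ZeroLibraryError(AlraError):
    """One or more cells have zero total counts and cannot be library-normalized."""


class NoSignalError(AlraError):
    """No singular-value spacing exceeds the noise threshold; the rank cannot be
    estimated automatically and must be supplied by the user."""


class UndefinedStatisticError(AlraError):
    """A requested statistic (rate, correlation, Gini coefficient) is undefined
    for the given input, e.g. an empty denominator or an all-zero vector."""
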