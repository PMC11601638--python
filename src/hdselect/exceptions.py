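"""Exception hierarchy for :mod:`hdselect`.

All errors derive from :class:`HDSelectError` so callers can catch the
package's failures with a single ``except`` clause; most also derive from
the matching builtin (``ValueError``/``KeyError``) for idiomatic handling.
"""


class HDSelectError(Exception):
    """Base class for all hdselect errors."""


class InvalidParameterError(HDSelectError, ValueError):
    """A configuration or algorithm parameter is outside its admissible range."""


class InvalidInputError(HDSelectError, ValueError):
    """An input object (dataset, vector sequence, table) violates a precondition."""


class OutOfRangeError(HDSelectError, ValueError):
    """A numeric value falls outside the quantisation range of a level registry."""


class UndefinedSimilarityError(HDSelectError, ValueError):
    """Cosine similarity was requested against an all-zero vector."""


class StratificationError(HDSelectError, ValueError):
    """Stratified cross-validation is impossible (some class smaller than k)."""


class OracleDomainError(HDSelectError, KeyError):
    """An injected accuracy oracle was queried with a feature subset it does not cover."""


class ProfileParseError(HDSelectError, ValueError):
    """An abundance or metadata table could not be parsed."""
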