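"""Exception hierarchy.

Everything raised on purpose by this package derives from :class:`Pre2PubError`,
so callers can catch one type at a tool boundary while tests assert on the
specific subclasses.
"""


class Pre2PubError(Exception):
    """Base class for all errors raised by pre2pub."""


class InvalidDOIError(Pre2PubError, ValueError):
    """Input does not contain a recognizable DOI (no ``10.`` prefix / no suffix)."""


class InvalidNameError(Pre2PubError, ValueError):
    """An author name with no usable content (empty family and raw form)."""


class SchemaError(Pre2PubError, ValueError):
    """A file is missing a required field/column; the message names it."""


class UndefinedSimilarityError(Pre2PubError, ArithmeticError):
    """Cosine similarity of two zero vectors; callers treat this as a non-match."""


class UndefinedMetricError(Pre2PubError, ArithmeticError):
    """Precision/recall/F1 requested with a zero denominator."""


class CorpusSpecError(Pre2PubError, ValueError):
    """Inconsistent synthetic-corpus specification (e.g. link fractions exceed published fraction)."""


class SourceError(Pre2PubError, RuntimeError):
    """A metadata source failed after bounded retries."""


class ConsistencyError(Pre2PubError, ValueError):
    """A link store or record violates an internal invariant (e.g. duplicate preprint DOI)."""


class ConfigError(Pre2PubError, ValueError):
    """Invalid run configuration; the message names the offending key."""
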