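"""Exception hierarchy shared across the package.

Every error raised by enzypred derives from :class:`EnzypredError` so that
callers (and the command-line layer) can catch package failures uniformly.
"""


class EnzypredError(Exception):
    """Base class for all enzypred errors."""


class FormatError(EnzypredError):
    """A file or table does not match the expected layout."""


class SchemaError(EnzypredError):
    """In-memory objects disagree on columns, lengths or feature ordering."""


class EmptyInputError(EnzypredError):
    """An operation received an empty collection where at least one item is required."""


class InsufficientDataError(EnzypredError):
    """Too few observations to fit the requested statistics."""


class DegenerateLabelsError(EnzypredError):
    """A binary-label operation received labels from a single class."""


class CoverageError(EnzypredError):
    """Substrates referenced by the reaction set lack descriptor rows."""


class DomainError(EnzypredError, ValueError):
    """A numeric argument is outside its documented domain."""


class EvaluationError(EnzypredError):
    """Cross-validation could not produce any evaluable fold."""
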