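"""Exception hierarchy.

All package errors derive from :class:`AnsbrError` so callers can catch one
base class; the CLI maps validation-type errors to exit code 2 and missing
inputs to exit code 3.
"""


class AnsbrError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(AnsbrError):
    """An input file could not be parsed (malformed header, bad newick, ...)."""


class ValidationError(AnsbrError):
    """Parsed data violates an invariant (negative value, duplicate id, ...)."""


class DomainError(AnsbrError, ValueError):
    """An argument is outside the mathematical domain of an operation."""


class InsufficientDataError(AnsbrError):
    """Not enough observations to perform the requested computation."""


class OutOfRangeError(AnsbrError):
    """A value (e.g. an operational day) falls outside every defined window."""


class UndefinedCorrelationError(DomainError):
    """Correlation undefined because one series has zero variance."""


class MissingInputError(AnsbrError):
    """A required input file does not exist."""
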