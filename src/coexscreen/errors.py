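"""Exception hierarchy for the coexscreen pipeline.

Every stage raises a subclass of :class:`CoexscreenError`, so callers (and the
CLI) can distinguish pipeline failures from programming errors.
"""


class CoexscreenError(Exception):
    """Base class for all coexscreen errors."""


class SpecificationError(CoexscreenError):
    """An invalid simulation or parameter specification."""


class FormatError(CoexscreenError):
    """A malformed input file (ragged rows, duplicate genes, bad values)."""


class GeneLookupError(CoexscreenError, KeyError):
    """A requested gene symbol is absent from a table or matrix."""

    def __str__(self) -> str:  # KeyError quotes its message; keep it readable
        return Exception.__str__(self)


class DomainError(CoexscreenError):
    """Input values outside the operation's domain (e.g. negative expression)."""


class EmptyResultError(CoexscreenError):
    """A filtering step removed everything."""
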