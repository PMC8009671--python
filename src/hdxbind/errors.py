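"""Exception hierarchy.

Every error raised on purpose by this package derives from :class:`HdxbindError`
so callers (and the CLI) can distinguish data/usage problems from bugs.
"""


class HdxbindError(Exception):
    """Base class for all package errors."""


class InvalidDesignError(HdxbindError, ValueError):
    """A simulation design violates one of its invariants."""


class ParseError(HdxbindError, ValueError):
    """A row of an input table could not be parsed.

    Attributes
    ----------
    line : int or None
        1-based line number within the offending file, if known.
    """

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class UnknownProteinError(HdxbindError, KeyError):
    """A record references a protein absent from the sequence database."""


class AlphabetError(HdxbindError, ValueError):
    """A sequence contains a non-canonical residue."""


class DegenerateReferenceError(HdxbindError, ZeroDivisionError):
    """Mex100 equals Mex0, so the deuterated fraction is undefined."""


class IncompleteReferenceError(HdxbindError, ValueError):
    """A peptide lacks the undeuterated (or out-exchange) reference record."""


class PairingError(HdxbindError, ValueError):
    """Two uptake curves do not describe the same peptide."""


class InsufficientReplicatesError(HdxbindError, ValueError):
    """Fewer than two replicates on one side of a significance test."""


class NoDataError(HdxbindError, ValueError):
    """An operation received an empty input collection."""


class EmptyTitrationError(HdxbindError, ValueError):
    """Every titration point was excluded by the noise filter."""


class FitFailureError(HdxbindError, RuntimeError):
    """A model fit did not converge.

    Carries the best residual seen across starts for diagnostics.
    """

    def __init__(self, message: str, best_residual: float | None = None):
        self.best_residual = best_residual
        super().__init__(message)


class DomainError(HdxbindError, ValueError):
    """An argument lies outside the mathematical domain of an operation."""
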