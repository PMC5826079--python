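"""Exception hierarchy.

``InputError`` subclasses map to CLI exit code 2 (bad usage/inputs); every
other ``MagtraceError`` maps to exit code 1 (runtime failure).
"""


class MagtraceError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class InputError(MagtraceError):
    """Invalid or inconsistent user-supplied input."""

    exit_code = 2


class InvalidQualityError(InputError):
    """Bin quality estimate outside its valid range."""


class DegenerateBinError(InputError):
    """Bin with no recovered coding sequences."""


class DomainError(InputError):
    """Argument outside the mathematical domain of an operation."""


class NewickParseError(InputError):
    """Malformed newick input; carries an approximate position when known."""

    def __init__(self, message, position=None):
        if position is not None:
            message = f"{message} (near position {position})"
        super().__init__(message)
        self.position = position


class HitParseError(InputError):
    """Malformed homology-hit row; carries the 1-based line number."""

    def __init__(self, message, line=None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


class GenerationError(MagtraceError):
    """Synthetic-data generation could not satisfy its constraints."""


class BoundedSearchError(MagtraceError):
    """Reconciliation search exceeded the configured event bound."""

    def __init__(self, bound, needed):
        super().__init__(
            f"minimum-cost scenario needs {needed} events, above the "
            f"configured bound of {bound}; raise max_events to proceed"
        )
        self.bound = bound
        self.needed = needed
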