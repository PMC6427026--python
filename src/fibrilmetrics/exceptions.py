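"""Exception hierarchy used across the package."""


class FibrilMetricsError(Exception):
    """Base class for all package errors."""


class ParameterError(FibrilMetricsError, ValueError):
    """A parameter violates a documented precondition."""


class InputError(FibrilMetricsError, ValueError):
    """An input object (structure, sequence, trace) is unusable for the operation."""


class FormatError(FibrilMetricsError, ValueError):
    """A file could not be parsed as the expected format."""


class ParseError(FormatError):
    """A tabular file has a malformed row; carries the 1-based line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class MutationMismatchError(InputError):
    """The stated wild-type residue does not match the sequence (numbering guard)."""


class ConstructionError(FibrilMetricsError, RuntimeError):
    """A synthetic object could not be built to satisfy its own guarantees."""


class FitError(FibrilMetricsError, RuntimeError):
    """A model fit failed to converge; message carries diagnostics."""
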