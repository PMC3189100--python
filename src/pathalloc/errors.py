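"""Exception hierarchy shared across the package."""


class PathallocError(Exception):
    """Base class for all package errors."""


class ParameterError(PathallocError, ValueError):
    """A parameter value is outside its allowed range."""


class InputError(PathallocError, ValueError):
    """Input data violates a structural precondition (shape, alignment, domain)."""


class FormatError(InputError):
    """A file could not be parsed; carries the offending line number when known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
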