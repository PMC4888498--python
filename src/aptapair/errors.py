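"""Exception types shared across the package."""


class AptapairError(Exception):
    """Base class for all package errors."""


class ParseError(AptapairError, ValueError):
    """A file could not be parsed; carries the offending line number when known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)


class ValidationError(AptapairError, ValueError):
    """Input content violates a domain invariant (alphabet, range, ...)."""


class DimensionError(AptapairError, ValueError):
    """A matrix or vector has the wrong shape for the declared object."""
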