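"""Exception hierarchy shared across the package."""


class DsSpectrumError(Exception):
    """Base class for all package errors."""


class ParseError(DsSpectrumError):
    """A file could not be parsed; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class ValidationError(DsSpectrumError):
    """Input values violate a documented invariant."""


class ConvergenceError(DsSpectrumError):
    """A model fit did not converge; no estimates are available."""


class InfeasibleError(DsSpectrumError):
    """A requested synthetic configuration is mathematically unattainable."""
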