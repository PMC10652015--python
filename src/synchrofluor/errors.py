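"""Exception hierarchy shared across the package."""


class SynchrofluorError(Exception):
    """Base class for all package-specific errors."""


class DomainError(SynchrofluorError, ValueError):
    """A wavelength or scan diagonal falls outside the measured domain."""


class DegenerateDesignError(SynchrofluorError, ValueError):
    """A regression design carries no information (e.g. one concentration)."""


class FormatError(SynchrofluorError, ValueError):
    """A file does not conform to the documented dialect.

    Carries the offending line number when known.
    """

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


class DataError(SynchrofluorError, ValueError):
    """A file parses but its contents violate a data contract."""
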