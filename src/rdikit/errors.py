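"""Exception hierarchy shared across the package.

The CLI maps these onto exit codes: :class:`ConfigurationError` -> 2,
:class:`DataError` (and subclasses) -> 3.
"""


class RdikitError(Exception):
    """Base class for all rdikit errors."""


class ConfigurationError(RdikitError):
    """A requested column, option or setting is invalid or inconsistent."""


class DataError(RdikitError):
    """Input data violate a precondition (empty rows, size mismatches...)."""


class ParseError(DataError):
    """A malformed input file; carries the offending line number when known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class CalibrationError(RdikitError):
    """Calibration could not produce a usable (monotone) model."""
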