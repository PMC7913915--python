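"""Exception hierarchy shared across the package.

Each class maps to a distinct CLI exit code so shell pipelines can tell
bad input (2) from a curve without detectable freezing events (3) and
from a model fit that failed to converge (4).
"""


class IcekinError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ValidationError(IcekinError):
    """Input violates a structural precondition (bad shapes, ordering, ranges)."""

    exit_code = 2


class ParseError(ValidationError):
    """A data file could not be parsed; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


class RangeError(ValidationError):
    """A value falls outside the domain of a packaged table or fitted map."""


class DetectionError(IcekinError):
    """A freezing event (supercooling, 0 degC crossing, ...) was not found."""

    exit_code = 3


class FitError(IcekinError):
    """Nonlinear least squares failed to converge after multistart."""

    exit_code = 4
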