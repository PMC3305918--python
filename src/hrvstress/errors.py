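"""Exception hierarchy shared by all hrvstress modules."""


class HRVError(Exception):
    """Base class for all hrvstress errors."""


class ValidationError(HRVError, ValueError):
    """An argument or parameter violates a documented precondition."""


class RRParseError(HRVError, ValueError):
    """An RR input file could not be parsed.

    Carries the 1-based line number of the offending line when known.
    """

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


class DegenerateSeriesError(HRVError, ValueError):
    """A series is too short or too uniform for the requested computation."""


class EstimationError(HRVError, ArithmeticError):
    """A regression/slope estimate is undefined for the given data."""


class PairingError(HRVError, ValueError):
    """A subject is missing one of its two sessions."""
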