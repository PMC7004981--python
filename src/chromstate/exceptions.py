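"""Exception hierarchy."""


class ChromstateError(Exception):
    """Base class for all package errors."""


class InputFormatError(ChromstateError):
    """An input file could not be read or decoded."""


class ValidationError(ChromstateError, ValueError):
    """A model component violates its construction invariants."""


class OutOfBoundsError(ChromstateError, ValueError):
    """An event falls outside the declared reference span."""


class BedParseError(InputFormatError):
    """A malformed BED line; carries the 1-based line number."""

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


class UndefinedMetricError(ChromstateError, ZeroDivisionError):
    """A QC or benchmark metric has an empty denominator."""


class AlignmentError(ChromstateError, ValueError):
    """Replicate tracks do not cover a common span."""


class NumericalError(ChromstateError, FloatingPointError):
    """Inference produced a non-finite quantity; names the base index."""
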