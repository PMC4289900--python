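"""Exception hierarchy.

All package errors derive from :class:`DendromapsError` so callers can catch
one base class; the CLI maps the three broad families (configuration,
numerical, I/O) onto distinct exit codes.
"""


class DendromapsError(Exception):
    """Base class for all dendromaps errors."""


class SwcParseError(DendromapsError):
    """Malformed SWC content (carries the offending line number)."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


class StructuralError(DendromapsError):
    """Morphology violates tree invariants (orphans, cycles, bad radii)."""


class ConfigurationError(DendromapsError):
    """Invalid or infeasible parameters / configuration."""


class NumericalError(DendromapsError):
    """Solver divergence, NaN/overflow during integration."""


class MeasurementError(DendromapsError):
    """A measurement protocol produced uninterpretable output."""
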