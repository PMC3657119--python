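"""Exception hierarchy for the lampvision pipeline.

Every stage raises a subclass of :class:`LampvisionError` so callers (and the
CLI) can distinguish bad user input from degenerate data or misconfiguration.
"""


class LampvisionError(Exception):
    """Base class for all package errors."""


class ValidationError(LampvisionError):
    """Input value violates a documented invariant (e.g. lambda_max bounds)."""


class ConfigurationError(LampvisionError):
    """Run configuration is inconsistent (e.g. grid does not cover the window)."""


class DegenerateCurveError(LampvisionError):
    """A sensitivity curve never attains the requested level, or the
    above-level region has zero width — no half-maximum range exists."""


class DegenerateSpectrumError(LampvisionError):
    """A lamp spectrum carries no signal after baseline correction."""


class FormatError(LampvisionError):
    """A spectrometer or species file could not be parsed; carries the
    offending line number where known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)


class DesignError(LampvisionError):
    """A regression design matrix is unusable (rank deficient, too few rows)."""
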