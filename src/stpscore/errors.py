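"""Exception hierarchy shared across the package."""


class StpError(Exception):
    """Base class for all stpscore errors."""


class ParseError(StpError):
    """A file could not be parsed; carries the offending line number when known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class CalibrationError(StpError):
    """Model calibration preconditions violated (empty label class, no usable genes)."""


class ScoringError(StpError):
    """Scoring contract violated (unfrozen model, empty gene overlap)."""


class ConfigError(StpError):
    """Invalid configuration: duplicate pathway names, missing metrics, bad bounds."""


class AnalysisError(StpError):
    """Statistical operation preconditions violated (empty group, zero variance, ...)."""
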