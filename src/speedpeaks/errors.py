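"""Exception hierarchy for the speedpeaks pipeline."""


class SpeedPeaksError(Exception):
    """Base class for all package-specific errors."""


class FormatError(SpeedPeaksError):
    """A kinematics file (or config file) is structurally malformed."""


class RecordingValidationError(SpeedPeaksError):
    """A Recording violates its invariants (e.g. non-uniform sampling)."""

    def __init__(self, message: str, frame: int | None = None):
        super().__init__(message)
        self.frame = frame


class ConfigError(SpeedPeaksError):
    """A pipeline or simulation configuration value is invalid."""


class PipelineError(SpeedPeaksError):
    """The analysis pipeline cannot proceed (e.g. too few touches)."""


class UndefinedRError(SpeedPeaksError):
    """R is undefined because the interval histogram is empty."""
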