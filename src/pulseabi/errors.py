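"""Exception hierarchy shared across the pipeline."""


class PulseAbiError(Exception):
    """Base class for all package errors."""


class ParseError(PulseAbiError, ValueError):
    """A sample-stream file could not be parsed."""


class EmptyInputError(PulseAbiError, ValueError):
    """An input file or sequence contained no usable data."""


class ConfigError(PulseAbiError, ValueError):
    """Invalid configuration or settings value."""


class SignalLengthError(PulseAbiError, ValueError):
    """Signal too short for the requested decomposition depth."""


class PolarityError(PulseAbiError, ValueError):
    """QRS polarity could not be determined (e.g. constant signal)."""


class InsufficientDataError(PulseAbiError, ValueError):
    """Too few beats/landmarks to compute the requested quantity."""


class InsufficientDurationError(PulseAbiError, ValueError):
    """Recording shorter than the required averaging window."""


class LandmarkOrderError(PulseAbiError, ValueError):
    """A PPG systolic point does not follow its ECG R-peak."""


class DomainError(PulseAbiError, ValueError):
    """Argument outside the mathematical domain (non-positive length/time)."""


class HeightRangeError(PulseAbiError, ValueError):
    """Height outside the validated range of the arterial-length model."""


class RankError(PulseAbiError, ValueError):
    """Not enough distinct support points for a least-squares fit."""


class FixtureError(PulseAbiError, ValueError):
    """Embedded validation table has an unexpected shape."""


class StageError(PulseAbiError, RuntimeError):
    """A pipeline stage failed; names the stage and chains the cause."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage '{stage}' failed: {cause}")
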