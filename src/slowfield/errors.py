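"""Exception hierarchy shared across the pipeline stages."""


class SlowfieldError(Exception):
    """Base class for all package-specific errors."""


class InvalidConfigError(SlowfieldError, ValueError):
    """A simulation or pipeline configuration violates its contract."""


class InsufficientBaselineError(SlowfieldError, ValueError):
    """The session is too short to estimate the 50-s baseline."""


class DegenerateChannelError(SlowfieldError, ValueError):
    """A channel has zero variance over the baseline; z-scoring undefined."""

    def __init__(self, channels):
        self.channels = list(channels)
        super().__init__(
            f"zero baseline SD in channel(s) {self.channels}; "
            "z-scored features are undefined for constant channels"
        )


class WindowBoundsError(SlowfieldError, ValueError):
    """A requested feature window lies (partly) outside the session."""


class StratificationError(SlowfieldError, ValueError):
    """A cross-validation fold or training set lacks a class."""


class CalibrationError(SlowfieldError, ValueError):
    """Threshold calibration cannot reach the requested false-positive rate."""

    def __init__(self, target, best_achievable):
        self.target = target
        self.best_achievable = best_achievable
        super().__init__(
            f"cannot reach a rest false-detection rate of {target}/min; "
            f"best achievable is {best_achievable:.3f}/min"
        )


class GeometryError(SlowfieldError, ValueError):
    """Source/sensor geometry violates the single-sphere forward model."""


class ConditioningError(SlowfieldError, ValueError):
    """The inverse problem is ill-conditioned; increase regularization."""


class EmptyLogError(SlowfieldError, ValueError):
    """A closed-loop log contains no events to score."""


class IncompleteTableError(SlowfieldError, ValueError):
    """A subjects-by-features accuracy table has missing cells."""


class UndefinedAccuracy(SlowfieldError):
    """Signals that an accuracy is undefined (zero qualifying events)."""


class SessionFormatError(SlowfieldError, ValueError):
    """A persisted session container does not match the expected schema."""
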