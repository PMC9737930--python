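"""Exception hierarchy shared across the toolkit."""


class IMUKitError(Exception):
    """Base class for all imukit errors."""


class InvalidConfigError(IMUKitError, ValueError):
    """A configuration value violates its documented constraints."""


class InvalidSizeError(IMUKitError, ValueError):
    """An input is too short / has an inadmissible shape."""


class DegenerateSignalError(IMUKitError, ValueError):
    """A signal is constant (zero covariance) where variation is required."""


class IncompleteSessionError(IMUKitError, ValueError):
    """A session is missing a (task, side, modality) block required by a feature builder."""


class NumericalFailureError(IMUKitError, FloatingPointError):
    """A sampler or filter produced non-finite values; carries the time index."""

    def __init__(self, message: str, time_index: int | None = None):
        super().__init__(message)
        self.time_index = time_index


class InvalidDesignError(IMUKitError, ValueError):
    """An evaluation design cannot be constructed (e.g. single-subject LOSO)."""


class InvalidTargetError(IMUKitError, ValueError):
    """A regression target has no usable values."""
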