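"""Exception and warning hierarchy for the facetouch package."""


class FaceTouchError(Exception):
    """Base class for all package errors."""


class ConfigError(FaceTouchError, ValueError):
    """Invalid configuration value (unknown handedness, bad bounds, ...)."""


class InvalidInputError(FaceTouchError, ValueError):
    """Input data violates a precondition (zero gravity vector, unsorted
    timestamps, negative durations, ...)."""


class CalibrationError(FaceTouchError):
    """Calibration could not be completed (too few samples)."""


class DegenerateEnvironmentError(CalibrationError):
    """Calibration data has zero variance, so no noise scale can be
    estimated.  Synthetic noiseless input is the typical cause; add sensor
    noise or set the threshold manually."""


class DetectorStateError(FaceTouchError, RuntimeError):
    """Detector used before calibration."""


class UndefinedMetricError(FaceTouchError, ZeroDivisionError):
    """A ratio metric was requested with an empty denominator."""


class SingularFieldError(FaceTouchError, ValueError):
    """Magnetic field evaluated at a source position."""


class NoFieldIncreaseWarning(UserWarning):
    """Phase-2 calibration saw no field increase over the baseline; the
    resulting threshold multiplier is ~0 and would alert constantly."""


class DegenerateInputWarning(UserWarning):
    """Zero-variance calibration input produced a zero threshold."""
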