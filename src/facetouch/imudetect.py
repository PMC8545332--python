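"""Accelerometer-only face-touch detection for magnetometer-less wearables.

Without a magnetic barrier the detector falls back on the movement pattern
itself: a face-touch ends with the hand *rising* into the unsafe
orientation box.  Per sample the pitch change

    phidot = phi[k] - phi[k-1]      [degrees per sample]

is compared against a noise threshold ``beta``; a ``+1`` mark is pushed
into a fixed 50-element *slope* ring when ``phidot > beta`` and ``-1``
otherwise.  A positive ring mean means the majority of the recent window
was upward motion ("rising"), and

    alert  <=>  orientation unsafe  and  rising

``beta`` is calibrated with the arm held still for ~2 s: it is three times
the sample standard deviation of the still-hand pitch rate, i.e. the 3-sigma
band of orientation sensor noise.  Because phidot is a per-sample
difference, beta scales with the sampling rate; calibrate and monitor at
the same rate.

This detector needs no accessory but, by construction, fires on *any*
face-directed arm raise — eating, drinking, combing — so its false-positive
rate is expected to dominate the magnetometer variant's.
"""

from __future__ import annotations

import warnings
from collections import deque
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import CalibrationError, DegenerateInputWarning, DetectorStateError
from .orientation import OrientationBounds, estimate_angles, is_unsafe

__all__ = ["ImuCalibration", "ImuDetector", "DEFAULT_SLOPE_WINDOW"]

DEFAULT_SLOPE_WINDOW = 50  # slope-ring length M
DEFAULT_CAL_CAPACITY = 200  # calibration buffer length N


@dataclass(frozen=True)
class ImuCalibration:
    """Pitch-rate threshold ``beta = 3 * sigma_phidot`` (degrees/sample)
    and the still-hand pitch-rate standard deviation it came from."""

    beta: float
    sigma_phidot: float

    def __post_init__(self) -> None:
        if self.beta < 0 or self.sigma_phidot < 0:
            raise CalibrationError("beta and sigma_phidot must be non-negative")


def calibrate_imu(accel_stream, capacity: int = DEFAULT_CAL_CAPACITY) -> ImuCalibration:
    """Calibrate the pitch-rate threshold from a still-arm recording.

    ``accel_stream`` is (n, 3) gravity triplets spanning ~2 s.  The pitch is
    computed per sample, differenced, and the last ``capacity`` differences
    form the calibration buffer; ``beta`` is three times their sample
    standard deviation.  A noiseless recording yields ``beta = 0`` with a
    :class:`DegenerateInputWarning` (the rising test then marks any upward
    pitch change).
    """
    if isinstance(accel_stream, pd.DataFrame):
        accel_stream = accel_stream[["ax", "ay", "az"]].to_numpy(dtype=float)
    accel = np.asarray(accel_stream, dtype=float)
    if accel.ndim != 2 or accel.shape[1] != 3:
        raise CalibrationError(f"expected (n, 3) gravity triplets, got {accel.shape}")
    if len(accel) < 2:
        raise CalibrationError("imu calibration needs at least 2 samples")
    phi = estimate_angles(accel).phi
    phidot = np.diff(phi)[-capacity:]
    if phidot.size < 2:
        raise CalibrationError("imu calibration needs at least 2 pitch-rate samples")
    sigma = float(phidot.std(ddof=1))
    if sigma == 0.0:
        warnings.warn(
            "zero pitch-rate variance during calibration; beta = 0",
            DegenerateInputWarning,
            stacklevel=2,
        )
    return ImuCalibration(beta=3.0 * sigma, sigma_phidot=sigma)


class ImuDetector:
    """Streaming inertial-only detector.

    ``process`` resets the slope ring first, so calls on separate streams
    are independent.  The ring starts filled with ``-1`` (non-rising), and
    the first monitored sample has no predecessor so its pitch rate is
    taken as 0.
    """

    def __init__(
        self,
        bounds: OrientationBounds,
        calibration: ImuCalibration | None = None,
        slope_window: int = DEFAULT_SLOPE_WINDOW,
    ) -> None:
        if slope_window < 1:
            raise ValueError("slope_window must be >= 1")
        self.bounds = bounds
        self.slope_window = int(slope_window)
        self.calibration = calibration
        self._slope: deque[int] = deque([-1] * self.slope_window, maxlen=self.slope_window)
        self._prev_phi: float | None = None
        self.rising = False
        self.alert = False
        self.safe_orientation = True

    def calibrate(self, accel_stream, capacity: int = DEFAULT_CAL_CAPACITY) -> ImuCalibration:
        self.calibration = calibrate_imu(accel_stream, capacity=capacity)
        self.reset()
        return self.calibration

    def reset(self) -> None:
        """Restore the fresh monitoring state (ring all -1, no history)."""
        if self.calibration is None:
            raise DetectorStateError("detector is not calibrated")
        self._slope = deque([-1] * self.slope_window, maxlen=self.slope_window)
        self._prev_phi = None
        self.rising = False
        self.alert = False
        self.safe_orientation = True

    def step(self, ax: float, ay: float, az: float) -> bool:
        """Advance one sample; returns the alert flag."""
        if self.calibration is None:
            raise DetectorStateError("calibrate before calling step()")
        angles = estimate_angles((ax, ay, az))
        unsafe = is_unsafe(angles, self.bounds)
        self.safe_orientation = not unsafe
        phidot = 0.0 if self._prev_phi is None else angles.phi - self._prev_phi
        self._prev_phi = angles.phi
        # deleteFirst happens implicitly: the deque is always at capacity
        self._slope.append(1 if phidot > self.calibration.beta else -1)
        self.rising = (sum(self._slope) / self.slope_window) > 0.0
        self.alert = unsafe and self.rising
        return self.alert

    def step_sample(self, sample) -> bool:
        return self.step(sample.ax, sample.ay, sample.az)

    def process(self, frame: pd.DataFrame) -> np.ndarray:
        """Run a stream (columns ``ax,ay,az``) from a fresh state; returns
        per-sample alert flags."""
        self.reset()
        cols = frame[["ax", "ay", "az"]].to_numpy(dtype=float)
        alerts = np.empty(len(cols), dtype=bool)
        for i, row in enumerate(cols):
            alerts[i] = self.step(*row)
        return alerts
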