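"""Magnetometer-based face-touch detection (the "virtual magnetic barrier").

The user wears a small necklace of permanent magnets below the face.  The
watch tracks the magnitude of the local magnetic field,

    Phi = sqrt(m_x**2 + m_y**2 + m_z**2)   [microtesla],

and maintains a background model of the environment — a ring buffer of the
last ``N = 200`` magnitudes updated **only while the wrist orientation is
safe**, from which a rolling mean ``phi_bar`` (over the last ``M = 50``
entries) and a sample standard deviation ``sigma_phi`` (over the full
buffer, N-1 divisor) are computed.  While the orientation is unsafe the
background model is frozen, and an alert fires whenever the standardised
deviation exceeds a calibrated multiplier:

    alert  <=>  orientation unsafe  and  |Phi - phi_bar| / sigma_phi > alpha

The alert clears as soon as either condition fails.

``alpha`` comes from a two-phase calibration: ~2 s with the arm extended far
from the magnets (baseline mean/std), then ~3 s slowly approaching the
necklace and stopping about 20 cm away (running maximum ``phi_hat``), giving
``alpha = |phi_hat - phi_bar| / sigma_phi`` — the largest standardised
excursion still considered "not a touch".  For a perfectly Gaussian
background alpha = 3 would already bound the false-alert rate near 0.3%
(the 99.7% three-sigma interval); real magnetic environments are burstier,
which is exactly what the calibration absorbs.
"""

from __future__ import annotations

import warnings
from collections import deque
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import (
    CalibrationError,
    DegenerateEnvironmentError,
    DetectorStateError,
    NoFieldIncreaseWarning,
)
from .orientation import OrientationBounds, WristAngles, estimate_angles, is_unsafe

__all__ = [
    "MagCalibration",
    "MagDetector",
    "field_magnitude",
    "DEFAULT_CAPACITY",
    "DEFAULT_MEAN_WINDOW",
]

DEFAULT_CAPACITY = 200  # ring-buffer length N
DEFAULT_MEAN_WINDOW = 50  # rolling-mean window M


def field_magnitude(mag) -> np.ndarray | float:
    """Euclidean magnitude of magnetometer triplet(s), microtesla."""
    m = np.asarray(mag, dtype=float)
    out = np.linalg.norm(m, axis=-1)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class MagCalibration:
    """Result of the two-phase magnetometer calibration.

    Attributes
    ----------
    phi_bar : float
        Baseline field magnitude mean, microtesla (phase 1).
    sigma_phi : float
        Baseline sample standard deviation, microtesla (phase 1).
    phi_hat : float
        Maximum magnitude observed during the approach (phase 2).
    alpha : float
        Threshold multiplier ``|phi_hat - phi_bar| / sigma_phi``.
    """

    phi_bar: float
    sigma_phi: float
    phi_hat: float
    alpha: float

    def __post_init__(self) -> None:
        if self.sigma_phi <= 0:
            raise DegenerateEnvironmentError(
                "sigma_phi must be > 0 after a successful calibration"
            )
        if self.alpha < 0:
            raise CalibrationError("alpha must be non-negative")


class MagDetector:
    """Streaming detector over accelerometer + magnetometer samples.

    Typical use::

        det = MagDetector(bounds_for("right"))
        det.calibrate_phase1(phase1_mag_triplets)
        det.calibrate_phase2(phase2_mag_triplets)
        alerts = det.process(stream_df)     # or det.step(...) sample by sample

    ``process`` resets the detector to its post-calibration state first, so
    repeated calls on different streams are independent.
    """

    def __init__(
        self,
        bounds: OrientationBounds,
        capacity: int = DEFAULT_CAPACITY,
        mean_window: int = DEFAULT_MEAN_WINDOW,
    ) -> None:
        if capacity < 2 or not (0 < mean_window <= capacity):
            raise ValueError("need capacity >= 2 and 0 < mean_window <= capacity")
        self.bounds = bounds
        self.capacity = int(capacity)
        self.mean_window = int(mean_window)
        self.calibration: MagCalibration | None = None
        self._buffer: deque[float] = deque(maxlen=self.capacity)
        self._calibrated_buffer: tuple[float, ...] = ()
        self.phi_bar = 0.0
        self.sigma_phi = 0.0
        self.alert = False
        self.safe_orientation = True

    # ------------------------------------------------------------------ #
    # calibration

    def calibrate_phase1(self, mag_stream) -> tuple[float, float]:
        """Prime the background buffer with the arm far from the magnets.

        ``mag_stream`` is an iterable of magnetometer triplets (n, 3) or a
        1-d array of precomputed magnitudes spanning the ~2 s phase.
        Returns ``(phi_bar, sigma_phi)`` computed over the primed buffer.
        """
        magnitudes = _as_magnitudes(mag_stream)
        if magnitudes.size < 2:
            raise CalibrationError("phase-1 calibration needs at least 2 samples")
        self._buffer.clear()
        for value in magnitudes:  # appendLast / removeFirst once full
            self._buffer.append(float(value))
        arr = np.array(self._buffer)
        phi_bar = float(arr.mean())
        sigma_phi = float(arr.std(ddof=1))
        if sigma_phi == 0.0:
            raise DegenerateEnvironmentError(
                "zero field variance during phase-1 calibration; add sensor "
                "noise or set alpha manually"
            )
        self.phi_bar, self.sigma_phi = phi_bar, sigma_phi
        self.calibration = None
        return phi_bar, sigma_phi

    def calibrate_phase2(self, mag_stream) -> MagCalibration:
        """Record the approach toward the necklace (stop ~20 cm away) and
        derive ``alpha``.  Phase 1 must have run first."""
        if self.sigma_phi <= 0.0:
            raise CalibrationError("run calibrate_phase1 before calibrate_phase2")
        magnitudes = _as_magnitudes(mag_stream)
        if magnitudes.size < 1:
            raise CalibrationError("phase-2 calibration needs at least 1 sample")
        phi_hat = float(magnitudes.max())
        if phi_hat <= self.phi_bar:
            warnings.warn(
                "no field increase observed during phase-2 calibration; "
                "alpha ~ 0 would alert on any deviation",
                NoFieldIncreaseWarning,
                stacklevel=2,
            )
        alpha = abs(phi_hat - self.phi_bar) / self.sigma_phi
        cal = MagCalibration(self.phi_bar, self.sigma_phi, phi_hat, alpha)
        self._install(cal, tuple(self._buffer))
        return cal

    @classmethod
    def from_calibration(
        cls,
        calibration: MagCalibration,
        bounds: OrientationBounds,
        buffer: Sequence[float] | None = None,
        capacity: int = DEFAULT_CAPACITY,
        mean_window: int = DEFAULT_MEAN_WINDOW,
    ) -> "MagDetector":
        """Build a ready-to-run detector from a stored calibration.

        Without an explicit buffer the background ring is primed with the
        calibration baseline mean (flat history with the calibrated
        mean/std retained until safe samples refresh it).
        """
        det = cls(bounds, capacity=capacity, mean_window=mean_window)
        if buffer is None:
            buffer = [calibration.phi_bar] * capacity
        det._install(calibration, tuple(float(v) for v in buffer))
        return det

    def _install(self, cal: MagCalibration, buffer: tuple[float, ...]) -> None:
        self.calibration = cal
        self._calibrated_buffer = buffer
        self._buffer = deque(buffer, maxlen=self.capacity)
        self.phi_bar = cal.phi_bar
        self.sigma_phi = cal.sigma_phi
        self.alert = False
        self.safe_orientation = True

    def reset(self) -> None:
        """Restore the post-calibration state (buffer, baseline, flags)."""
        if self.calibration is None:
            raise DetectorStateError("detector is not calibrated")
        self._install(self.calibration, self._calibrated_buffer)

    # ------------------------------------------------------------------ #
    # monitoring

    def step(self, ax: float, ay: float, az: float, mx: float, my: float, mz: float) -> bool:
        """Advance one sample; returns the alert flag.

        Safe orientation: the magnitude enters the ring buffer and the
        rolling baseline is refreshed, never alerting.  Unsafe orientation:
        buffer and baseline stay frozen and the standardised-deviation
        predicate decides the alert (strict ``>``; a tie does not alert).
        """
        if self.calibration is None:
            raise DetectorStateError("calibrate before calling step()")
        angles = estimate_angles((ax, ay, az))
        unsafe = is_unsafe(angles, self.bounds)
        self.safe_orientation = not unsafe
        phi = float(np.sqrt(mx * mx + my * my + mz * mz))
        if self.safe_orientation:
            if len(self._buffer) == self.capacity:
                self._buffer.popleft()
            self._buffer.append(phi)
            arr = np.array(self._buffer)
            self.phi_bar = float(arr[-self.mean_window:].mean())
            sigma = float(arr.std(ddof=1))
            # a constant buffer (possible when primed flat from a stored
            # calibration) carries no noise scale; keep the calibrated one
            self.sigma_phi = sigma if sigma > 0.0 else self.calibration.sigma_phi
            self.alert = False
        else:
            self.alert = abs(phi - self.phi_bar) / self.sigma_phi > self.calibration.alpha
        return self.alert

    def step_sample(self, sample) -> bool:
        """Step from a :class:`facetouch.io.SensorSample`-like record."""
        return self.step(sample.ax, sample.ay, sample.az, sample.mx, sample.my, sample.mz)

    def process(self, frame: pd.DataFrame) -> np.ndarray:
        """Run the stream (columns ``ax,ay,az,mx,my,mz``) from a fresh
        post-calibration state; returns the per-sample alert flags."""
        self.reset()
        cols = frame[["ax", "ay", "az", "mx", "my", "mz"]].to_numpy(dtype=float)
        alerts = np.empty(len(cols), dtype=bool)
        for i, row in enumerate(cols):
            alerts[i] = self.step(*row)
        return alerts


def _as_magnitudes(stream) -> np.ndarray:
    """Accept (n, 3) triplets, a 1-d magnitude array, or an iterable of
    either; return a 1-d magnitude array."""
    if isinstance(stream, pd.DataFrame):
        stream = stream[["mx", "my", "mz"]].to_numpy(dtype=float)
    elif isinstance(stream, Iterable) and not isinstance(stream, np.ndarray):
        stream = np.asarray(list(stream), dtype=float)
    arr = np.asarray(stream, dtype=float)
    if arr.ndim == 2 and arr.shape[1] == 3:
        return np.linalg.norm(arr, axis=1)
    if arr.ndim == 1:
        return arr
    raise CalibrationError(f"expected (n, 3) triplets or magnitudes, got shape {arr.shape}")
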