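"""Wrist roll/pitch estimation from the gravity vector and safe/unsafe gating.

A smartwatch accelerometer at rest senses the gravity vector in the sensor
frame.  Roll ``theta`` and pitch ``phi`` follow from the standard gravity
decomposition

    theta = atan2(a_y, a_z) * 180/pi
    phi   = atan2(-a_x, sqrt(a_y**2 + a_z**2)) * 180/pi

in the aeronautical North-East-Down convention (z down, aligned with
gravity).  Yaw is unobservable from gravity alone and is deliberately not
estimated: a hand can reach the face at any yaw, so yaw carries no
discriminative information for this task.

Not every wrist orientation is compatible with a natural hand-to-face
movement.  The *unsafe* orientation box — the roll/pitch region a wrist
passes through while the hand approaches the face — is an open rectangle in
(theta, phi).  For a watch worn on the left (right-handed user's
non-dominant) arm the box is ``-90 < theta < 70`` and ``30 < phi < 100``
degrees; worn on the other arm the box is mirrored (both angles negated).
Orientations outside the box are *safe*: the detectors use safe stretches to
learn the magnetic background and never alert there.

Angles are kept in degrees throughout.  Only ratios of acceleration
components matter, so streams expressed in g instead of m/s^2 give
identical angles.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import NamedTuple

import numpy as np
import yaml

from .exceptions import ConfigError, InvalidInputError

__all__ = [
    "WristAngles",
    "OrientationBounds",
    "estimate_angles",
    "is_unsafe",
    "bounds_for",
    "load_bounds",
]

#: Default unsafe-box boundaries, degrees: (theta_min, theta_max, phi_min, phi_max)
RIGHT_HANDED_BOUNDS = (-90.0, 70.0, 30.0, 100.0)
LEFT_HANDED_BOUNDS = (-70.0, 90.0, -100.0, -30.0)


class WristAngles(NamedTuple):
    """Wrist attitude: roll ``theta`` in (-180, 180], pitch ``phi`` in
    [-90, 90], both degrees.  Fields may be scalars or aligned arrays."""

    theta: float
    phi: float


@dataclass(frozen=True)
class OrientationBounds:
    """Open roll/pitch box that delimits *unsafe* (face-touch-compatible)
    wrist orientations, in degrees."""

    theta_min: float
    theta_max: float
    phi_min: float
    phi_max: float
    handedness: str = "right"

    def __post_init__(self) -> None:
        if not (self.theta_min < self.theta_max and self.phi_min < self.phi_max):
            raise ConfigError(
                "orientation bounds require theta_min < theta_max and "
                f"phi_min < phi_max, got {self}"
            )
        if self.handedness not in ("right", "left"):
            raise ConfigError(f"unknown handedness {self.handedness!r}")

    @classmethod
    def for_handedness(cls, handedness: str) -> "OrientationBounds":
        if handedness == "right":
            return cls(*RIGHT_HANDED_BOUNDS, handedness="right")
        if handedness == "left":
            return cls(*LEFT_HANDED_BOUNDS, handedness="left")
        raise ConfigError(f"unknown handedness {handedness!r}; expected 'right' or 'left'")

    def mirror(self) -> "OrientationBounds":
        """Bounds for the opposite wrist: both angles negated, which swaps
        and negates each (min, max) pair."""
        return OrientationBounds(
            theta_min=-self.theta_max,
            theta_max=-self.theta_min,
            phi_min=-self.phi_max,
            phi_max=-self.phi_min,
            handedness="left" if self.handedness == "right" else "right",
        )

    def replace(self, **kwargs) -> "OrientationBounds":
        return replace(self, **kwargs)


def bounds_for(handedness: str) -> OrientationBounds:
    """Default unsafe-box bounds for a ``'right'`` or ``'left'``-handed user
    (watch on the non-dominant wrist)."""
    return OrientationBounds.for_handedness(handedness)


def load_bounds(source: str | Path | dict) -> OrientationBounds:
    """Load bounds from a YAML/JSON mapping or file.

    Recognised keys: ``handedness`` plus optional per-angle overrides
    ``theta_min``, ``theta_max``, ``phi_min``, ``phi_max`` (degrees).
    """
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            source = yaml.safe_load(fh)
    if not isinstance(source, dict):
        raise ConfigError("bounds config must be a mapping")
    handedness = source.get("handedness", "right")
    bounds = OrientationBounds.for_handedness(handedness)
    overrides = {
        k: float(source[k])
        for k in ("theta_min", "theta_max", "phi_min", "phi_max")
        if k in source
    }
    return bounds.replace(**overrides) if overrides else bounds


def estimate_angles(gravity) -> WristAngles:
    """Roll/pitch in degrees from gravity components ``(a_x, a_y, a_z)``.

    ``gravity`` is array-like with shape ``(3,)`` or ``(n, 3)``; in the
    latter case the returned fields are arrays.  A zero-magnitude triplet
    signals sensor dropout and raises :class:`InvalidInputError`.
    ``atan2(0, 0)`` is taken as 0 (library convention), so degenerate but
    non-zero readings still yield angles.
    """
    g = np.asarray(gravity, dtype=float)
    if g.shape[-1] != 3:
        raise InvalidInputError(f"expected gravity triplet(s), got shape {g.shape}")
    magnitude = np.linalg.norm(g, axis=-1)
    if np.any(magnitude == 0.0):
        raise InvalidInputError("zero-magnitude gravity triplet (sensor dropout?)")
    a_x, a_y, a_z = np.moveaxis(g, -1, 0)
    theta = np.degrees(np.arctan2(a_y, a_z))
    phi = np.degrees(np.arctan2(-a_x, np.hypot(a_y, a_z)))
    if theta.ndim == 0:
        return WristAngles(float(theta), float(phi))
    return WristAngles(theta, phi)


def is_unsafe(angles: WristAngles, bounds: OrientationBounds):
    """True iff the orientation falls strictly inside the unsafe box,
    i.e. is compatible with a face-touch.  Boundary values are safe
    (strict inequalities, matching the alert gating)."""
    theta = np.asarray(angles.theta)
    phi = np.asarray(angles.phi)
    unsafe = (
        (bounds.theta_min < theta)
        & (theta < bounds.theta_max)
        & (bounds.phi_min < phi)
        & (phi < bounds.phi_max)
    )
    if unsafe.ndim == 0:
        return bool(unsafe)
    return unsafe
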