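"""Synthetic smartwatch sensor streams for face-touch detection studies.

The simulator emulates what a watch-worn accelerometer and magnetometer see
while the wrist follows a scripted gesture near a magnet necklace:

* **Necklace field** — each magnet is a point dipole; the necklace field is
  the superposition of the five dipoles plus a uniform Earth field.  The
  default dipole moment is *calibrated* so a single magnet produces the
  bench-measured ~420 uT on axis at 5 cm; the nominal N42-remanence moment
  (which over-predicts the near-field of a real disc magnet) is available
  via :meth:`MagnetSpec.nominal_moment`.
* **Wrist trajectory** — gesture scripts are keyframes of wrist position
  (metres, necklace frame) and roll/pitch (degrees).  Position blends with
  a minimum-jerk profile between keyframes; angles interpolate linearly.
* **Sensor model** — the accelerometer reads the gravity vector rotated
  into the sensor frame plus white noise; the magnetometer reads the local
  field rotated into the sensor frame plus white noise and optional
  Poisson-timed exponentially decaying EMF bursts (default off).

Frames: the world frame is North-East-Down with its origin at the central
magnet, x pointing horizontally away from the chest and z down; magnet
moments all point along +x.  Gravity is (0, 0, 9.81) m/s^2.

All randomness flows from a single seed; regeneration is bit-identical.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .exceptions import ConfigError, InvalidInputError, SingularFieldError
from .orientation import OrientationBounds, bounds_for

__all__ = [
    "MagnetSpec",
    "NecklaceModel",
    "SimConfig",
    "Keyframe",
    "GestureScript",
    "SimStream",
    "dipole_field",
    "calibrated_moment",
    "generate_stream",
    "make_benchmark",
    "face_touch_script",
    "adl_script",
    "rest_script",
    "approach_script",
    "ADL_KINDS",
]

MU0_OVER_4PI = 1e-7  # T * m / A
GRAVITY = 9.81  # m/s^2


# --------------------------------------------------------------------- #
# magnetostatics


def calibrated_moment(field_uT: float = 420.0, distance_m: float = 0.05) -> float:
    """Dipole moment (A*m^2) whose on-axis field at ``distance_m`` equals
    ``field_uT``: on axis B = 2e-7 * m / r^3."""
    return field_uT * 1e-6 * distance_m**3 / (2.0 * MU0_OVER_4PI)


@dataclass(frozen=True)
class MagnetSpec:
    """One necklace magnet: a 10 mm x 5 mm N42 disc.

    ``dipole_moment`` defaults to the bench-calibrated value (~0.2625
    A*m^2, i.e. 420 uT on axis at 5 cm)."""

    diameter_mm: float = 10.0
    thickness_mm: float = 5.0
    grade: str = "N42"
    dipole_moment: float = calibrated_moment()

    def __post_init__(self) -> None:
        if self.dipole_moment <= 0:
            raise ConfigError("dipole_moment must be positive")

    def nominal_moment(self, remanence_T: float = 1.32) -> float:
        """Moment from nominal grade remanence, m = Br * V / mu0."""
        r = self.diameter_mm * 1e-3 / 2.0
        volume = math.pi * r * r * self.thickness_mm * 1e-3
        return remanence_T * volume / (4.0 * math.pi * MU0_OVER_4PI)


def dipole_field(moment, source_pos, point) -> np.ndarray:
    """Point-dipole field in microtesla at ``point`` (metres).

    ``moment`` is the dipole moment vector in A*m^2 (or a scalar, taken
    along +x).  Supports broadcasting over points with shape (..., 3).
    Evaluating at the source raises :class:`SingularFieldError`.
    """
    m = np.asarray(moment, dtype=float)
    if m.ndim == 0:
        m = np.array([float(m), 0.0, 0.0])
    r = np.asarray(point, dtype=float) - np.asarray(source_pos, dtype=float)
    dist = np.linalg.norm(r, axis=-1, keepdims=True)
    if np.any(dist == 0.0):
        raise SingularFieldError("field requested at the magnet position")
    rhat = r / dist
    m_dot_r = np.sum(m * rhat, axis=-1, keepdims=True)
    tesla = MU0_OVER_4PI * (3.0 * rhat * m_dot_r - m) / dist**3
    return tesla * 1e6


@dataclass(frozen=True)
class NecklaceModel:
    """Five aligned disc magnets on a shallow arc in the chest plane.

    Magnets sit 4.5 cm apart (neighbour chord distance) on an arc of
    radius ``arc_radius_m`` sagging toward the central magnet at the
    origin; all moments point along +x (out of the chest).
    """

    magnet_count: int = 5
    spacing_cm: float = 4.5
    arc_radius_m: float = 0.18
    magnet: MagnetSpec = field(default_factory=MagnetSpec)

    def __post_init__(self) -> None:
        if self.magnet_count < 1:
            raise ConfigError("magnet_count must be >= 1")
        if self.spacing_cm <= 0 or self.arc_radius_m <= 0:
            raise ConfigError("spacing and arc radius must be positive")

    def positions(self) -> np.ndarray:
        """(count, 3) magnet positions, metres, world frame."""
        step = 2.0 * math.asin(self.spacing_cm * 1e-2 / (2.0 * self.arc_radius_m))
        offsets = (np.arange(self.magnet_count) - (self.magnet_count - 1) / 2.0) * step
        r = self.arc_radius_m
        return np.column_stack(
            [
                np.zeros_like(offsets),
                r * np.sin(offsets),
                -r * (1.0 - np.cos(offsets)),  # ends curve up toward the neck
            ]
        )

    def moments(self) -> np.ndarray:
        """(count, 3) dipole moment vectors, A*m^2."""
        m = np.zeros((self.magnet_count, 3))
        m[:, 0] = self.magnet.dipole_moment
        return m

    def field_at(self, points, earth_field=None) -> np.ndarray:
        """Superposed necklace field (uT) at world points (..., 3), plus an
        optional uniform Earth-field vector."""
        points = np.asarray(points, dtype=float)
        total = np.zeros(np.broadcast_shapes(points.shape, (3,)), dtype=float)
        for pos, mom in zip(self.positions(), self.moments()):
            total = total + dipole_field(mom, pos, points)
        if earth_field is not None:
            total = total + np.asarray(earth_field, dtype=float)
        return total


# --------------------------------------------------------------------- #
# configuration and scripts


@dataclass(frozen=True)
class SimConfig:
    """Sensor/environment configuration.

    ``earth_field_uT`` defaults to 45, the middle of the 25-60 uT surface
    range; ``earth_inclination_deg`` tilts the field below the horizontal.
    Noise levels are white-noise standard deviations per axis typical of
    consumer MEMS parts at 100 Hz.  ``seed`` is mandatory: every random
    draw in the simulator flows from it.
    """

    sample_rate_hz: float = 100.0
    earth_field_uT: float = 45.0
    earth_inclination_deg: float = 60.0
    accel_noise_sd: float = 0.02  # m/s^2
    mag_noise_sd: float = 1.0  # uT
    emf_burst_rate_hz: float = 0.0
    emf_burst_amp_uT: float = 8.0
    emf_burst_tau_s: float = 0.05
    touch_proximity_m: float = 0.12
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sample_rate_hz <= 0:
            raise ConfigError("sample_rate_hz must be positive")
        if not 0.0 <= self.earth_field_uT:
            raise ConfigError("earth_field_uT must be non-negative")
        if self.seed is None:
            raise ConfigError("a seed is mandatory for reproducibility")

    def earth_vector(self) -> np.ndarray:
        """Uniform Earth field vector in the world (NED) frame, uT."""
        inc = math.radians(self.earth_inclination_deg)
        return self.earth_field_uT * np.array([math.cos(inc), 0.0, math.sin(inc)])

    @classmethod
    def from_yaml(cls, source: str | Path | dict) -> "SimConfig":
        if isinstance(source, (str, Path)):
            with open(source) as fh:
                source = yaml.safe_load(fh)
        return cls(**(source or {}))


@dataclass(frozen=True)
class Keyframe:
    """Wrist pose at time ``t``: position (m, world frame) and roll/pitch
    (degrees)."""

    t: float
    pos: tuple[float, float, float]
    theta: float
    phi: float


@dataclass(frozen=True)
class GestureScript:
    """Declarative wrist trajectory with a ground-truth label.

    ``label`` is one of ``face_touch``, ``adl``, ``rest``,
    ``calibration_phase1``, ``calibration_phase2``; ``script_id`` carries
    the concrete gesture (e.g. ``adl_mug_004``).  ``contact_window`` marks
    the [start, end] seconds during which a face-touch is in progress.
    """

    label: str
    duration_s: float
    keyframes: tuple[Keyframe, ...]
    contact_window: tuple[float, float] | None = None
    script_id: str = ""

    LABELS = ("face_touch", "adl", "rest", "calibration_phase1", "calibration_phase2")

    def __post_init__(self) -> None:
        if self.label not in self.LABELS:
            raise ConfigError(f"unknown script label {self.label!r}")
        if self.duration_s <= 0:
            raise InvalidInputError("script duration must be positive")
        times = [k.t for k in self.keyframes]
        if len(times) < 2 or any(b <= a for a, b in zip(times, times[1:])):
            raise InvalidInputError("keyframe times must be strictly increasing")
        if times[0] < 0 or times[-1] > self.duration_s:
            raise InvalidInputError("keyframes must lie within [0, duration]")

    def validate_face_touch(self, bounds: OrientationBounds, proximity_m: float) -> None:
        """Face-touch scripts must end their reach inside the unsafe box and
        within the proximity radius of the necklace centre."""
        if self.label != "face_touch":
            return
        if self.contact_window is None:
            raise ConfigError("face_touch script needs a contact_window")
        k = self.pose_at(self.contact_window[0])
        theta, phi, pos = k
        inside = bounds.theta_min < theta < bounds.theta_max and bounds.phi_min < phi < bounds.phi_max
        if not inside:
            raise ConfigError(f"face_touch script {self.script_id} ends outside the unsafe box")
        if float(np.linalg.norm(pos)) > proximity_m:
            raise ConfigError(
                f"face_touch script {self.script_id} ends farther than {proximity_m} m from the necklace"
            )

    def pose_at(self, t: float) -> tuple[float, float, np.ndarray]:
        """(theta, phi, position) at time ``t`` by interpolation."""
        theta, phi, pos = _interpolate(self.keyframes, np.array([t]))
        return float(theta[0]), float(phi[0]), pos[0]


def _minimum_jerk(tau: np.ndarray) -> np.ndarray:
    return tau**3 * (10.0 - 15.0 * tau + 6.0 * tau * tau)


def _interpolate(keyframes: Sequence[Keyframe], times: np.ndarray):
    """Piecewise interpolation: minimum-jerk position blend, linear angles.
    Times outside the keyframe span clamp to the end poses."""
    kt = np.array([k.t for k in keyframes])
    kpos = np.array([k.pos for k in keyframes])
    ktheta = np.array([k.theta for k in keyframes])
    kphi = np.array([k.phi for k in keyframes])
    idx = np.clip(np.searchsorted(kt, times, side="right") - 1, 0, len(keyframes) - 2)
    t0, t1 = kt[idx], kt[idx + 1]
    tau = np.clip((times - t0) / (t1 - t0), 0.0, 1.0)
    s = _minimum_jerk(tau)
    pos = kpos[idx] + s[:, None] * (kpos[idx + 1] - kpos[idx])
    theta = ktheta[idx] + tau * (ktheta[idx + 1] - ktheta[idx])
    phi = kphi[idx] + tau * (kphi[idx + 1] - kphi[idx])
    return theta, phi, pos


def _world_to_sensor(theta_deg: np.ndarray, phi_deg: np.ndarray) -> np.ndarray:
    """(n, 3, 3) rotation matrices mapping world (NED) vectors into the
    sensor frame for roll theta, pitch phi, yaw 0."""
    th = np.radians(theta_deg)
    ph = np.radians(phi_deg)
    ct, st = np.cos(th), np.sin(th)
    cp, sp = np.cos(ph), np.sin(ph)
    n = len(th)
    rot = np.empty((n, 3, 3))
    # Rx(-theta) @ Ry(-phi)
    rot[:, 0, 0] = cp
    rot[:, 0, 1] = 0.0
    rot[:, 0, 2] = -sp
    rot[:, 1, 0] = st * sp
    rot[:, 1, 1] = ct
    rot[:, 1, 2] = st * cp
    rot[:, 2, 0] = ct * sp
    rot[:, 2, 1] = -st
    rot[:, 2, 2] = ct * cp
    return rot


@dataclass
class SimStream:
    """A generated stream: sensor data (``t,ax,ay,az,mx,my,mz``), a sidecar
    label table (``t,label,script_id``), and the source script."""

    script: GestureScript
    data: pd.DataFrame
    labels: pd.DataFrame

    @property
    def duration_s(self) -> float:
        return self.script.duration_s


def generate_stream(
    script: GestureScript,
    necklace: NecklaceModel,
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
) -> SimStream:
    """Render a gesture script into a labelled sensor stream.

    A fresh generator is derived from ``cfg.seed`` unless ``rng`` is given
    (as :func:`make_benchmark` does to stream many scripts from one seed).
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    n = int(round(script.duration_s * cfg.sample_rate_hz))
    if n < 1:
        raise InvalidInputError("script too short for the configured sample rate")
    t = np.arange(n) / cfg.sample_rate_hz
    theta, phi, pos = _interpolate(script.keyframes, t)
    rot = _world_to_sensor(theta, phi)

    gravity_world = np.array([0.0, 0.0, GRAVITY])
    accel = rot @ gravity_world + rng.normal(0.0, cfg.accel_noise_sd, size=(n, 3))

    field_world = necklace.field_at(pos, earth_field=cfg.earth_vector())
    if cfg.emf_burst_rate_hz > 0.0:
        field_world = field_world + _emf_bursts(t, cfg, rng)
    mag = np.einsum("nij,nj->ni", rot, field_world)
    mag = mag + rng.normal(0.0, cfg.mag_noise_sd, size=(n, 3))

    data = pd.DataFrame(
        {
            "t": t,
            "ax": accel[:, 0],
            "ay": accel[:, 1],
            "az": accel[:, 2],
            "mx": mag[:, 0],
            "my": mag[:, 1],
            "mz": mag[:, 2],
        }
    )
    labels = pd.DataFrame({"t": t, "label": script.label, "script_id": script.script_id})
    return SimStream(script=script, data=data, labels=labels)


def _emf_bursts(t: np.ndarray, cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Poisson-timed bursts of exponentially decaying amplitude along
    random directions (models appliance/EMF disturbances)."""
    duration = t[-1] + 1.0 / cfg.sample_rate_hz
    n_bursts = rng.poisson(cfg.emf_burst_rate_hz * duration)
    out = np.zeros((len(t), 3))
    for _ in range(n_bursts):
        t0 = rng.uniform(0.0, duration)
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        amp = rng.exponential(cfg.emf_burst_amp_uT)
        mask = t >= t0
        out[mask] += amp * np.exp(-(t[mask] - t0) / cfg.emf_burst_tau_s)[:, None] * direction
    return out


# --------------------------------------------------------------------- #
# script library

#: Start pose: hand at the side, safe orientation, far from the necklace.
_REST_POS = np.array([0.10, 0.20, 0.45])
_REST_ANGLES = (0.0, -75.0)

ADL_KINDS = ("spoon", "mug", "comb", "shirt")

# target direction (world frame, unit-normalised at use), distance range (m),
# final roll / pitch (deg) and their jitter half-widths
_ADL_TABLE = {
    "spoon": ((0.60, 0.10, -0.25), (0.29, 0.33), 15.0, 8.0, 52.0, 6.0),
    "mug": ((0.55, 0.05, -0.30), (0.26, 0.30), 5.0, 8.0, 58.0, 6.0),
    "comb": ((0.30, 0.35, -0.55), (0.31, 0.35), -25.0, 8.0, 68.0, 8.0),
    "shirt": ((0.50, 0.00, 0.25), (0.25, 0.29), 25.0, 10.0, 40.0, 5.0),
}

_TOUCH_DIRECTION = (0.55, 0.08, -0.35)
_TOUCH_DISTANCE = (0.065, 0.095)


def _unit(v) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    return v / np.linalg.norm(v)


def _jitter(rng: np.random.Generator, value: float, half_width: float) -> float:
    return float(value + rng.uniform(-half_width, half_width))


#: People pre-orient the wrist while raising the arm: the rotation finishes
#: within the first ``_ROTATION_FRACTION`` of the reach while the hand has
#: barely started translating (it holds position for ``_POSITION_LAG`` of
#: the reach).  The orientation therefore crosses into the unsafe box while
#: the hand is still far from the face, which is what lets the detectors
#: freeze a clean background model before the field rises.
_POSITION_LAG = 0.45
_ROTATION_FRACTION = 0.60


def _reach_keyframes(
    t1: float, t2: float, rest_pos, target, rest_angles, theta_f: float, phi_f: float
) -> tuple[Keyframe, ...]:
    """Reach segment: wrist rotation leads, hand translation lags."""
    d = t2 - t1
    tm = t1 + _POSITION_LAG * d
    tr = t1 + _ROTATION_FRACTION * d
    frac = _POSITION_LAG / _ROTATION_FRACTION  # rotation progress at tm
    theta_m = rest_angles[0] + frac * (theta_f - rest_angles[0])
    phi_m = rest_angles[1] + frac * (phi_f - rest_angles[1])
    rest_arr = np.asarray(rest_pos, dtype=float)
    p_r = tuple(rest_arr + 0.12 * (np.asarray(target) - rest_arr))
    return (
        Keyframe(t1, tuple(rest_pos), *rest_angles),
        Keyframe(tm, tuple(rest_pos), theta_m, phi_m),
        Keyframe(tr, p_r, theta_f, phi_f),
        Keyframe(t2, tuple(target), theta_f, phi_f),
    )


def face_touch_script(rng: np.random.Generator, script_id: str = "face_touch_000") -> GestureScript:
    """Reach from the resting pose to the face (wrist 6.5-9.5 cm from the
    necklace centre), hold, and retract.  Timing and end pose are jittered
    per call."""
    reach = _jitter(rng, 0.7, 0.07)
    hold = _jitter(rng, 0.7, 0.07)
    retract = _jitter(rng, 0.6, 0.06)
    t1 = _jitter(rng, 0.4, 0.04)
    t2, t3 = t1 + reach, t1 + reach + hold
    duration = t3 + retract
    target = _unit(_TOUCH_DIRECTION) * rng.uniform(*_TOUCH_DISTANCE)
    theta_f = _jitter(rng, 15.0, 15.0)
    phi_f = _jitter(rng, 62.0, 8.0)
    rest_pos = tuple(_REST_POS + rng.uniform(-0.02, 0.02, size=3))
    keyframes = (
        Keyframe(0.0, rest_pos, *_REST_ANGLES),
        *_reach_keyframes(t1, t2, rest_pos, target, _REST_ANGLES, theta_f, phi_f),
        Keyframe(t3, tuple(target), theta_f, phi_f),
        Keyframe(duration, rest_pos, *_REST_ANGLES),
    )
    return GestureScript(
        label="face_touch",
        duration_s=duration,
        keyframes=keyframes,
        contact_window=(t2, t3),
        script_id=script_id,
    )


def adl_script(kind: str, rng: np.random.Generator, script_id: str = "") -> GestureScript:
    """An activity-of-daily-living confounder: the wrist *enters* the
    unsafe orientation box while rising but stays well outside the
    face-touch proximity radius of the necklace."""
    if kind not in _ADL_TABLE:
        raise ConfigError(f"unknown ADL kind {kind!r}; options: {ADL_KINDS}")
    direction, dist_range, theta_f, theta_j, phi_f, phi_j = _ADL_TABLE[kind]
    reach = _jitter(rng, 0.8, 0.08)
    manipulate = _jitter(rng, 1.0, 0.1)
    back = _jitter(rng, 0.7, 0.07)
    t1 = _jitter(rng, 0.4, 0.04)
    t2 = t1 + reach
    t3 = t2 + manipulate
    duration = t3 + back
    target = _unit(direction) * rng.uniform(*dist_range)
    theta_f = _jitter(rng, theta_f, theta_j)
    phi_f = _jitter(rng, phi_f, phi_j)
    rest_pos = tuple(_REST_POS + rng.uniform(-0.02, 0.02, size=3))
    # mid-manipulation wiggle (spoonfuls, sips, comb strokes)
    mid_pos = tuple(np.asarray(target) + rng.uniform(-0.02, 0.02, size=3))
    keyframes = (
        Keyframe(0.0, rest_pos, *_REST_ANGLES),
        *_reach_keyframes(t1, t2, rest_pos, target, _REST_ANGLES, theta_f, phi_f),
        Keyframe((t2 + t3) / 2.0, mid_pos, theta_f, _jitter(rng, phi_f, 8.0)),
        Keyframe(t3, tuple(target), theta_f, phi_f),
        Keyframe(duration, rest_pos, *_REST_ANGLES),
    )
    return GestureScript(
        label="adl",
        duration_s=duration,
        keyframes=keyframes,
        contact_window=None,
        script_id=script_id or f"adl_{kind}_000",
    )


def rest_script(duration_s: float = 2.0, distance_m: float = 0.55, label: str = "rest") -> GestureScript:
    """Arm held still far from the necklace (also the phase-1 and inertial
    calibration posture, with the arm extended in front)."""
    pos = tuple(_unit((0.9, 0.1, 0.3)) * distance_m)
    keyframes = (
        Keyframe(0.0, pos, 0.0, 0.0),
        Keyframe(duration_s, pos, 0.0, 0.0),
    )
    return GestureScript(label=label, duration_s=duration_s, keyframes=keyframes, script_id=label)


def approach_script(
    duration_s: float = 3.0, stop_distance_m: float = 0.20, start_distance_m: float = 0.55
) -> GestureScript:
    """Phase-2 calibration movement: slowly bring the watch toward the
    necklace, stopping ~20 cm away."""
    u = _unit((0.9, 0.1, 0.3))
    keyframes = (
        Keyframe(0.0, tuple(u * start_distance_m), 0.0, 0.0),
        Keyframe(duration_s, tuple(u * stop_distance_m), 0.0, 0.0),
    )
    return GestureScript(
        label="calibration_phase2",
        duration_s=duration_s,
        keyframes=keyframes,
        script_id="calibration_phase2",
    )


def calibration_scripts(
    phase1_s: float = 2.0, phase2_s: float = 3.0
) -> tuple[GestureScript, GestureScript]:
    """The 2 s + 3 s magnetometer calibration pair (arm far, then approach
    to ~20 cm)."""
    p1 = replace(rest_script(phase1_s, label="calibration_phase1"), script_id="calibration_phase1")
    return p1, approach_script(phase2_s)


def make_benchmark(
    n_touch: int = 30,
    n_adl: int = 30,
    necklace: NecklaceModel | None = None,
    cfg: SimConfig | None = None,
    seed: int | None = None,
    bounds: OrientationBounds | None = None,
) -> list[SimStream]:
    """The in-silico detection benchmark: ``n_touch`` face-touch gestures
    and ``n_adl`` ADL gestures (cycled over the built-in library), in
    pseudorandom order, all driven by a single seed.

    Face-touch scripts are validated to end inside the unsafe box and
    within ``cfg.touch_proximity_m`` of the necklace.
    """
    if n_touch < 1 or n_adl < 1:
        raise ConfigError("need at least one gesture of each class")
    necklace = necklace or NecklaceModel()
    cfg = cfg or SimConfig()
    if seed is not None:
        cfg = replace(cfg, seed=int(seed))
    bounds = bounds or bounds_for("right")
    rng = np.random.default_rng(cfg.seed)
    scripts: list[GestureScript] = [
        face_touch_script(rng, f"face_touch_{i:03d}") for i in range(n_touch)
    ]
    for i in range(n_adl):
        kind = ADL_KINDS[i % len(ADL_KINDS)]
        scripts.append(adl_script(kind, rng, f"adl_{kind}_{i:03d}"))
    order = rng.permutation(len(scripts))
    streams = []
    for idx in order:
        script = scripts[idx]
        script.validate_face_touch(bounds, cfg.touch_proximity_m)
        streams.append(generate_stream(script, necklace, cfg, rng=rng))
    return streams
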