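"""Independent batch re-implementations used as oracles.

Deliberately written with a different toolset than the package (pure
Python ``math``/``statistics`` loops instead of numpy state machines) so
streaming/batch agreement is a meaningful cross-check.
"""

import math
from statistics import fmean, stdev

import numpy as np
from scipy import stats


def batch_angles(ax, ay, az):
    theta = math.degrees(math.atan2(ay, az))
    phi = math.degrees(math.atan2(-ax, math.hypot(ay, az)))
    return theta, phi


def _unsafe(theta, phi, bounds):
    return (
        bounds.theta_min < theta < bounds.theta_max
        and bounds.phi_min < phi < bounds.phi_max
    )


def batch_mag_calibration(phase1_mags, phase2_mags, capacity=200):
    """Two-phase calibration recomputed from raw magnitude lists."""
    buf = list(phase1_mags)[-capacity:]
    phi_bar = fmean(buf)
    sigma = stdev(buf)
    phi_hat = max(phase2_mags)
    return phi_bar, sigma, phi_hat, abs(phi_hat - phi_bar) / sigma


def batch_mag_alerts(frame, phase1_mags, alpha, bounds, capacity=200, window=50):
    """Full alert sequence of the magnetic-barrier detector, recomputed
    batch-wise from the stream table and the phase-1 priming magnitudes."""
    buf = list(phase1_mags)[-capacity:]
    phi_bar = fmean(buf)
    sigma = stdev(buf)
    alerts = []
    rows = frame[["ax", "ay", "az", "mx", "my", "mz"]].itertuples(index=False)
    for ax, ay, az, mx, my, mz in rows:
        theta, phi = batch_angles(ax, ay, az)
        mag = math.sqrt(mx * mx + my * my + mz * mz)
        if not _unsafe(theta, phi, bounds):
            if len(buf) == capacity:
                buf.pop(0)
            buf.append(mag)
            phi_bar = fmean(buf[-window:])
            sigma = stdev(buf)
            alerts.append(False)
        else:
            alerts.append(abs(mag - phi_bar) / sigma > alpha)
    return np.array(alerts, dtype=bool)


def batch_imu_beta(accel, capacity=200):
    """Pitch-rate threshold recomputed from a still-arm recording."""
    phis = [batch_angles(*row)[1] for row in accel]
    diffs = [b - a for a, b in zip(phis, phis[1:])][-capacity:]
    return 3.0 * stdev(diffs)


def batch_imu_alerts(frame, beta, bounds, ring_length=50):
    """Full alert sequence of the inertial detector."""
    ring = [-1] * ring_length
    prev_phi = None
    alerts = []
    for ax, ay, az in frame[["ax", "ay", "az"]].itertuples(index=False):
        theta, phi = batch_angles(ax, ay, az)
        phidot = 0.0 if prev_phi is None else phi - prev_phi
        prev_phi = phi
        ring.pop(0)
        ring.append(1 if phidot > beta else -1)
        rising = fmean(ring) > 0.0
        alerts.append(_unsafe(theta, phi, bounds) and rising)
    return np.array(alerts, dtype=bool)


def welford_mean_std(values):
    """One-pass mean and sample standard deviation."""
    mean = 0.0
    m2 = 0.0
    n = 0
    for v in values:
        n += 1
        delta = v - mean
        mean += delta / n
        m2 += delta * (v - mean)
    return mean, math.sqrt(m2 / (n - 1))


def mc_paired_power(n, dz, alpha=0.05, sims=20000, seed=0):
    """Monte-Carlo power of the two-sided paired t-test: simulate paired
    differences ~ N(dz, 1) and count rejections."""
    rng = np.random.default_rng(seed)
    diffs = rng.normal(dz, 1.0, size=(sims, n))
    t = diffs.mean(axis=1) / (diffs.std(ddof=1, axis=1) / math.sqrt(n))
    tcrit = stats.t.ppf(1.0 - alpha / 2.0, n - 1)
    return float(np.mean(np.abs(t) > tcrit))
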