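"""Event segmentation, touch classification, detection metrics, and the
statistical battery for comparing monitoring conditions.

Per-sample alert flags are segmented into maximal alert events.  Each event
is classified by duration: shorter than one second it is a *Touch Attempt*
(TA) — the user aborted the gesture in time — otherwise it is a *Happened
Contact* (HC), whose recorded duration is the time in excess of one second.
Exactly 1 s classifies as HC (a TA is defined as lasting *less* than a
second; the complement is HC).

Detection accuracy on a labelled benchmark counts a face-touch gesture as
correctly detected when at least one alert sample falls inside its contact
window (with a small matching tolerance), and an activity-of-daily-living
gesture as a false positive when it triggers any alert at all.

The condition-comparison battery mirrors a standard within-subject
protocol: paired-samples t-tests on per-subject rates, a Shapiro-Wilk
normality gate with a square-root fallback transform, and post-hoc power of
the paired t-test from the noncentral t distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import InvalidInputError, UndefinedMetricError

__all__ = [
    "AlertEvent",
    "TouchEvent",
    "MetricsReport",
    "StatsReport",
    "DetectionResult",
    "segment_alerts",
    "classify_touch",
    "detect_streams",
    "detection_metrics",
    "paired_t",
    "normality_gate",
    "posthoc_power",
    "compare_conditions",
    "gaussian_coverage",
]

TA_THRESHOLD_S = 1.0


@dataclass(frozen=True)
class AlertEvent:
    """A maximal run of alert samples: [start_s, end_s] in stream time."""

    start_s: float
    end_s: float

    def __post_init__(self) -> None:
        if self.end_s < self.start_s:
            raise InvalidInputError("event end before start")

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass(frozen=True)
class TouchEvent:
    """Classified alert event: ``kind`` is ``'TA'`` (duration < 1 s) or
    ``'HC'`` (duration >= 1 s, recorded duration = excess over 1 s)."""

    kind: str
    recorded_duration_s: float
    event: AlertEvent


def segment_alerts(t, alerts, min_gap_s: float = 0.0) -> list[AlertEvent]:
    """Turn a timestamped boolean alert series into events.

    Maximal runs of True become events; consecutive events separated by a
    gap shorter than ``min_gap_s`` merge (default 0: never merge).
    Timestamps must be sorted.
    """
    t = np.asarray(t, dtype=float)
    alerts = np.asarray(alerts, dtype=bool)
    if t.shape != alerts.shape:
        raise InvalidInputError("timestamps and alert flags must align")
    if np.any(np.diff(t) < 0):
        raise InvalidInputError("timestamps must be sorted")
    if t.size == 0:
        return []
    padded = np.concatenate([[False], alerts, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    starts, ends = edges[::2], edges[1::2] - 1
    events: list[AlertEvent] = []
    for s, e in zip(starts, ends):
        ev = AlertEvent(float(t[s]), float(t[e]))
        if events and ev.start_s - events[-1].end_s < min_gap_s:
            events[-1] = AlertEvent(events[-1].start_s, ev.end_s)
        else:
            events.append(ev)
    return events


def classify_touch(event: AlertEvent, threshold_s: float = TA_THRESHOLD_S) -> TouchEvent:
    """Classify an alert event as Touch Attempt or Happened Contact."""
    duration = event.duration_s
    if duration < 0:
        raise InvalidInputError("negative event duration")
    if duration < threshold_s:
        return TouchEvent("TA", duration, event)
    return TouchEvent("HC", duration - threshold_s, event)


# --------------------------------------------------------------------- #
# benchmark metrics


@dataclass(frozen=True)
class DetectionResult:
    """Detector output over one labelled stream."""

    script_id: str
    label: str
    t: np.ndarray
    alerts: np.ndarray
    contact_window: tuple[float, float] | None = None


def detect_streams(detector, streams: Iterable) -> list[DetectionResult]:
    """Run a calibrated detector over simulated streams.

    ``detector`` needs ``process(frame) -> alert flags`` (which both
    bundled detectors implement, resetting state per stream).
    """
    results = []
    for stream in streams:
        alerts = detector.process(stream.data)
        results.append(
            DetectionResult(
                script_id=stream.script.script_id,
                label=stream.script.label,
                t=stream.data["t"].to_numpy(),
                alerts=np.asarray(alerts, dtype=bool),
                contact_window=stream.script.contact_window,
            )
        )
    return results


@dataclass(frozen=True)
class MetricsReport:
    """Benchmark detection accuracy and event-rate summary."""

    correct_detection_pct: float
    false_positive_pct: float
    n_touch: int
    n_adl: int
    ta_per_hour: float
    hc_per_hour: float
    hc_durations: tuple[float, ...] = ()
    monitored_hours: float = 0.0

    def __post_init__(self) -> None:
        for pct in (self.correct_detection_pct, self.false_positive_pct):
            if not 0.0 <= pct <= 100.0:
                raise InvalidInputError("percentages must lie in [0, 100]")
        if self.ta_per_hour < 0 or self.hc_per_hour < 0:
            raise InvalidInputError("rates must be non-negative")


def detection_metrics(
    results: Sequence[DetectionResult],
    window_tolerance_s: float = 0.5,
    min_gap_s: float = 0.0,
) -> MetricsReport:
    """Score detector output against ground-truth gesture labels.

    A face-touch counts as correctly detected if any alert sample falls
    inside its contact window widened by ``window_tolerance_s`` on both
    sides; an ADL gesture with any alert counts as a false positive.
    TA/HC rates are per hour of total monitored time across all streams.
    """
    touches = [r for r in results if r.label == "face_touch"]
    adls = [r for r in results if r.label == "adl"]
    if not touches or not adls:
        raise UndefinedMetricError("benchmark needs both face-touch and ADL streams")

    hits = 0
    for r in touches:
        if r.contact_window is None:
            raise InvalidInputError(f"face-touch stream {r.script_id} lacks a contact window")
        lo = r.contact_window[0] - window_tolerance_s
        hi = r.contact_window[1] + window_tolerance_s
        in_window = (r.t >= lo) & (r.t <= hi)
        if np.any(r.alerts & in_window):
            hits += 1
    false_pos = sum(bool(np.any(r.alerts)) for r in adls)

    dt_hours = 0.0
    ta = hc = 0
    hc_durations: list[float] = []
    for r in results:
        if len(r.t) > 1:
            dt_hours += (r.t[-1] - r.t[0] + (r.t[1] - r.t[0])) / 3600.0
        for event in segment_alerts(r.t, r.alerts, min_gap_s=min_gap_s):
            touch = classify_touch(event)
            if touch.kind == "TA":
                ta += 1
            else:
                hc += 1
                hc_durations.append(touch.recorded_duration_s)

    return MetricsReport(
        correct_detection_pct=100.0 * hits / len(touches),
        false_positive_pct=100.0 * false_pos / len(adls),
        n_touch=len(touches),
        n_adl=len(adls),
        ta_per_hour=ta / dt_hours if dt_hours > 0 else 0.0,
        hc_per_hour=hc / dt_hours if dt_hours > 0 else 0.0,
        hc_durations=tuple(hc_durations),
        monitored_hours=dt_hours,
    )


# --------------------------------------------------------------------- #
# statistics


class PairedTResult(NamedTuple):
    mean_diff: float
    t: float
    df: int
    p: float


def paired_t(x, y) -> PairedTResult:
    """Classical paired-samples t-test on ``x - y`` (two-sided)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise InvalidInputError("paired_t needs two equal-length 1-d samples, n >= 2")
    diffs = x - y
    if diffs.std(ddof=1) == 0.0:
        raise InvalidInputError("zero-variance differences: paired t undefined")
    res = stats.ttest_rel(x, y)
    return PairedTResult(float(diffs.mean()), float(res.statistic), x.size - 1, float(res.pvalue))


class NormalityGateResult(NamedTuple):
    w: float
    p: float
    transformed: bool
    w_raw: float
    p_raw: float


def normality_gate(values, alpha: float = 0.05) -> NormalityGateResult:
    """Shapiro-Wilk test with square-root fallback.

    The raw sample is tested first; if it fails at ``alpha`` the test is
    repeated on square-rooted values (requires non-negative data) and the
    ``transformed`` flag is set.  ``w``/``p`` refer to the test that
    stands (transformed when the fallback ran).
    """
    values = np.asarray(values, dtype=float)
    if values.size < 3:
        raise InvalidInputError("Shapiro-Wilk needs at least 3 values")
    if np.ptp(values) == 0.0:
        raise InvalidInputError("constant input: W undefined")
    w_raw, p_raw = stats.shapiro(values)
    if p_raw > alpha:
        return NormalityGateResult(float(w_raw), float(p_raw), False, float(w_raw), float(p_raw))
    if np.any(values < 0):
        raise InvalidInputError("square-root transform requested for negative values")
    w_t, p_t = stats.shapiro(np.sqrt(values))
    return NormalityGateResult(float(w_t), float(p_t), True, float(w_raw), float(p_raw))


def posthoc_power(
    n: int, effect_size_dz: float, alpha: float = 0.05, two_sided: bool = True
) -> float:
    """Power of the paired t-test for effect size ``dz`` (mean difference
    over the SD of differences) at sample size ``n``.

    Uses the noncentral t distribution with ``ncp = dz * sqrt(n)`` and
    ``df = n - 1``.
    """
    if n < 2:
        raise InvalidInputError("need n >= 2")
    if effect_size_dz <= 0:
        raise InvalidInputError("effect size must be positive")
    if not 0.0 < alpha < 1.0:
        raise InvalidInputError("alpha must lie in (0, 1)")
    df = n - 1
    ncp = effect_size_dz * np.sqrt(n)
    if two_sided:
        tcrit = stats.t.ppf(1.0 - alpha / 2.0, df)
        # the opposite-sign rejection region is vanishingly small at large
        # ncp, where scipy's lower-tail CDF can underflow to nan
        lower = stats.nct.cdf(-tcrit, df, ncp)
        power = stats.nct.sf(tcrit, df, ncp) + (0.0 if np.isnan(lower) else lower)
    else:
        tcrit = stats.t.ppf(1.0 - alpha, df)
        power = stats.nct.sf(tcrit, df, ncp)
    return float(power)


@dataclass(frozen=True)
class StatsReport:
    """One condition comparison: paired t on per-subject values of a
    metric under two monitoring conditions, normality diagnostics, and
    post-hoc power from the observed effect size."""

    metric: str
    mean_diff: float
    t: float
    df: int
    p: float
    shapiro_w_raw: float
    shapiro_p_raw: float
    shapiro_w: float
    shapiro_p: float
    transformed: bool
    power: float
    extra: dict = field(default_factory=dict)


def compare_conditions(x, y, metric: str = "", alpha: float = 0.05) -> StatsReport:
    """Full battery for one metric (non-negative per-subject rates or
    durations): Shapiro-Wilk gate on each condition's data with a
    square-root fallback, paired t-test on the (possibly transformed)
    samples, and post-hoc power at the observed ``dz = |t| / sqrt(n)``.
    Reported normality diagnostics are for the pooled data."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    gate = normality_gate(np.concatenate([x, y]), alpha=alpha)
    if gate.transformed:
        x_used, y_used = np.sqrt(x), np.sqrt(y)
    else:
        x_used, y_used = x, y
    test = paired_t(x_used, y_used)
    dz = abs(test.t) / np.sqrt(x.size)
    power = posthoc_power(x.size, dz, alpha=alpha) if dz > 0 else alpha
    return StatsReport(
        metric=metric,
        mean_diff=test.mean_diff,
        t=test.t,
        df=test.df,
        p=test.p,
        shapiro_w_raw=gate.w_raw,
        shapiro_p_raw=gate.p_raw,
        shapiro_w=gate.w,
        shapiro_p=gate.p,
        transformed=gate.transformed,
        power=power,
    )


def gaussian_coverage(values, k: float = 3.0) -> float:
    """Fraction of a sample within ``mean +/- k * std`` (sample std).  For
    Gaussian data and k = 3 this approaches 99.7%."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise InvalidInputError("coverage needs at least 2 values")
    mu = values.mean()
    sd = values.std(ddof=1)
    return float(np.mean(np.abs(values - mu) <= k * sd))
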