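"""Event segmentation, TA/HC classification, benchmark metrics, and the
statistical battery."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from facetouch.evalstats import (
    AlertEvent,
    DetectionResult,
    classify_touch,
    compare_conditions,
    detection_metrics,
    gaussian_coverage,
    normality_gate,
    paired_t,
    posthoc_power,
    segment_alerts,
)
from facetouch.exceptions import InvalidInputError, UndefinedMetricError

from .oracles import mc_paired_power


class TestSegmentation:
    def test_adjacent_runs_merge_within_gap(self):
        t = np.round(np.arange(0.0, 3.0, 0.01), 10)
        flags = ((t >= 1.0) & (t <= 1.4)) | ((t >= 1.5) & (t <= 2.0))
        events = segment_alerts(t, flags, min_gap_s=0.2)  # 0.1 s gap merges
        assert len(events) == 1
        assert events[0].start_s == pytest.approx(1.0)
        assert events[0].end_s == pytest.approx(2.0)

    def test_no_merge_with_zero_gap(self):
        t = np.round(np.arange(0.0, 3.0, 0.01), 10)
        flags = ((t >= 1.0) & (t <= 1.4)) | ((t >= 1.5) & (t <= 2.0))
        assert len(segment_alerts(t, flags, min_gap_s=0.0)) == 2

    def test_all_false_gives_no_events(self):
        assert segment_alerts(np.arange(10.0), np.zeros(10, dtype=bool)) == []

    def test_alternating_samples_each_become_events(self):
        t = np.arange(0.0, 1.0, 0.01)
        flags = np.zeros(t.size, dtype=bool)
        flags[::2] = True
        events = segment_alerts(t, flags, min_gap_s=0.0)
        assert len(events) == flags.sum()
        assert all(e.duration_s == 0.0 for e in events)

    def test_unsorted_timestamps_rejected(self):
        with pytest.raises(InvalidInputError):
            segment_alerts([0.0, 2.0, 1.0], [True, True, True])


class TestTouchClassification:
    @pytest.mark.parametrize(
        "duration, kind, recorded",
        [
            (0.8, "TA", 0.8),  # attempts last less than a second
            (2.5, "HC", 1.5),  # excess over the 1 s threshold
            (1.0, "HC", 0.0),  # boundary classifies as contact
        ],
    )
    def test_duration_rule(self, duration, kind, recorded):
        touch = classify_touch(AlertEvent(10.0, 10.0 + duration))
        assert touch.kind == kind
        assert touch.recorded_duration_s == pytest.approx(recorded)

    def test_negative_duration_rejected(self):
        with pytest.raises(InvalidInputError):
            AlertEvent(2.0, 1.0)

    @given(st.lists(st.floats(0.0, 5.0), min_size=1, max_size=30))
    def test_partition_exhaustive_and_exclusive(self, durations):
        touches = [classify_touch(AlertEvent(0.0, d)) for d in durations]
        kinds = [t.kind for t in touches]
        assert all(k in ("TA", "HC") for k in kinds)
        assert kinds.count("TA") + kinds.count("HC") == len(durations)


def _result(label, alerted, script_id="s", window=None):
    t = np.arange(0.0, 3.0, 0.01)
    alerts = np.zeros(t.size, dtype=bool)
    if alerted:
        alerts[150:160] = True  # 0.1 s burst at t = 1.5
    return DetectionResult(script_id, label, t, alerts, window)


class TestDetectionMetrics:
    def test_correct_detection_ratio(self):
        touches = [
            _result("face_touch", i < 27, f"ft{i}", window=(1.0, 2.0)) for i in range(30)
        ]
        adls = [_result("adl", False, f"adl{i}") for i in range(30)]
        report = detection_metrics(touches + adls)
        assert report.correct_detection_pct == pytest.approx(90.0)
        assert report.false_positive_pct == pytest.approx(0.0)

    def test_alert_outside_window_not_correct(self):
        touches = [_result("face_touch", True, window=(2.5, 2.9))]  # burst at 1.5
        adls = [_result("adl", False)]
        report = detection_metrics(touches + adls, window_tolerance_s=0.5)
        assert report.correct_detection_pct == 0.0

    def test_any_adl_alert_is_false_positive(self):
        touches = [_result("face_touch", True, window=(1.0, 2.0))]
        adls = [_result("adl", True), _result("adl", False)]
        report = detection_metrics(touches + adls)
        assert report.false_positive_pct == pytest.approx(50.0)

    def test_permutation_invariance(self):
        results = [
            _result("face_touch", True, f"ft{i}", window=(1.0, 2.0)) for i in range(5)
        ] + [_result("adl", i % 2 == 0, f"adl{i}") for i in range(5)]
        fwd = detection_metrics(results)
        rev = detection_metrics(results[::-1])
        assert fwd == rev

    def test_empty_benchmark_rejected(self):
        with pytest.raises(UndefinedMetricError):
            detection_metrics([_result("adl", False)])

    def test_rates_and_durations(self):
        touches = [_result("face_touch", True, window=(1.0, 2.0))]
        adls = [_result("adl", False)]
        report = detection_metrics(touches + adls)
        # one 0.09 s event in 6 s of monitoring
        assert report.ta_per_hour == pytest.approx(1 / (6.0 / 3600.0))
        assert report.hc_per_hour == 0.0
        assert report.hc_durations == ()


class TestPairedT:
    def test_hand_computed_example(self):
        """diffs (1, 2, 1): mean 4/3, sd 0.5774, t = 4.0 on 2 df."""
        res = paired_t([2.0, 4.0, 5.0], [1.0, 2.0, 4.0])
        assert res.mean_diff == pytest.approx(4.0 / 3.0)
        assert res.t == pytest.approx(4.0, rel=1e-9)
        assert res.df == 2

    def test_antisymmetry(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=10), rng.normal(size=10)
        fwd, rev = paired_t(x, y), paired_t(y, x)
        assert fwd.mean_diff == pytest.approx(-rev.mean_diff)
        assert fwd.t == pytest.approx(-rev.t)
        assert fwd.p == pytest.approx(rev.p)

    def test_identical_samples_degenerate(self):
        with pytest.raises(InvalidInputError):
            paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])

    def test_printed_group_means_reduction(self):
        """The within-subject rate reduction implied by group means 25.18
        and 17.53 is 7.65 events/hour."""
        assert 25.18 - 17.53 == pytest.approx(7.65)


class TestNormalityGate:
    def test_lognormal_sample_triggers_sqrt_transform(self):
        """Frozen seeded lognormal (n=60): the raw sample fails Shapiro-
        Wilk, the square-rooted sample passes.  Reference W and p values
        computed independently with R stats::shapiro.test."""
        rng = np.random.default_rng(0)
        x = rng.lognormal(mean=1.0, sigma=0.4, size=60)
        res = normality_gate(x)
        assert res.transformed is True
        assert res.w_raw == pytest.approx(0.946428728852, abs=1e-9)
        assert res.p_raw == pytest.approx(0.0106157612821, abs=1e-8)
        assert res.w == pytest.approx(0.975896833844, abs=1e-9)
        assert res.p == pytest.approx(0.280169969587, abs=1e-8)
        assert res.p > 0.05

    def test_normal_sample_passes_untransformed(self):
        rng = np.random.default_rng(1)
        res = normality_gate(rng.normal(10.0, 2.0, size=60))
        assert res.transformed is False
        assert res.p > 0.05

    def test_square_root_transform_values(self):
        assert np.sqrt([4.0, 9.0, 25.0]).tolist() == [2.0, 3.0, 5.0]

    def test_constant_input_rejected(self):
        with pytest.raises(InvalidInputError):
            normality_gate([3.0, 3.0, 3.0, 3.0])

    def test_negative_values_cannot_transform(self):
        values = np.concatenate([[-5.0], np.full(20, 0.001), [50.0, 60.0, 70.0]])
        with pytest.raises(InvalidInputError):
            normality_gate(values)


class TestPosthocPower:
    def test_null_limit_approaches_alpha(self):
        assert posthoc_power(10, 1e-9, alpha=0.05) == pytest.approx(0.05, abs=1e-6)

    def test_monotone_in_sample_size(self):
        powers = [posthoc_power(n, 0.8) for n in range(2, 51)]
        assert all(b >= a for a, b in zip(powers, powers[1:]))

    def test_observed_effect_reaches_printed_power(self):
        """n = 10 with the observed paired-t statistic 4.77 (dz = 4.77 /
        sqrt(10)) gives power >= 0.8, in agreement with a Monte-Carlo
        oracle."""
        dz = 4.77 / np.sqrt(10)
        power = posthoc_power(10, dz)
        assert power >= 0.8
        assert power == pytest.approx(mc_paired_power(10, dz, sims=20000, seed=0), abs=0.01)

    def test_against_statsmodels(self):
        from statsmodels.stats.power import TTestPower

        dz, n = 0.9, 12
        reference = TTestPower().power(effect_size=dz, nobs=n, alpha=0.05, alternative="two-sided")
        assert posthoc_power(n, dz) == pytest.approx(float(reference), abs=1e-8)

    def test_invalid_alpha_rejected(self):
        with pytest.raises(InvalidInputError):
            posthoc_power(10, 0.5, alpha=1.5)


class TestConditionComparison:
    def test_full_battery_on_rate_data(self):
        rng = np.random.default_rng(21)
        control = rng.normal(25.0, 9.0, size=10).clip(min=0.1)
        feedback = control - rng.normal(7.0, 3.0, size=10)
        feedback = feedback.clip(min=0.1)
        report = compare_conditions(control, feedback, metric="ta_per_hour")
        assert report.df == 9
        assert report.mean_diff > 0
        assert 0.0 <= report.power <= 1.0

    def test_three_sigma_coverage_of_gaussian(self):
        rng = np.random.default_rng(2)
        cov = gaussian_coverage(rng.standard_normal(200_000))
        p = 0.9973002
        se = np.sqrt(p * (1 - p) / 200_000)
        assert abs(cov - p) < 3 * se
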