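"""Firing power and the three alarm strategies."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chronofp.postproc import (FiringPowerCurve, alarms_chronological,
                               alarms_control, alarms_cumulative, firing_power,
                               sum_curves)

MIN = 60.0


def brute_force_fp(O, tau):
    return np.array([np.mean(O[max(0, n - tau + 1): n + 1])
                     for n in range(len(O))])


def _step_curve(n, step_indices, high=0.6, times=None):
    """Curve that rises above 0.5 at each step index and stays up."""
    fp = np.zeros(n)
    for i in step_indices:
        fp[i:] = high
    if times is None:
        times = np.arange(n) * 5.0
    return FiringPowerCurve(fp=fp, times=times, tau=1)


class TestFiringPower:
    def test_all_zero_stream(self):
        c = firing_power(np.zeros(20, int), tau=4)
        assert np.all(c.fp == 0.0)

    def test_all_one_stream_saturates(self):
        c = firing_power(np.ones(20, int), tau=4)
        assert np.all(c.fp[3:] == 1.0)

    def test_worked_example(self):
        c = firing_power(np.array([0, 0, 1, 1, 0, 1]), tau=4)
        assert c.fp[-1] == pytest.approx(3 / 4)

    def test_warmup_mean_vs_zero(self):
        O = np.array([1, 1, 0, 0, 0])
        assert firing_power(O, 4, warmup="mean").fp[0] == 1.0
        assert firing_power(O, 4, warmup="zero").fp[0] == 0.0

    def test_empty_stream_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            firing_power(np.array([], dtype=int), tau=2)

    def test_nonbinary_rejected(self):
        with pytest.raises(ValueError, match="binary"):
            firing_power(np.array([0, 2, 1]), tau=2)

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(st.lists(st.integers(0, 1), min_size=1, max_size=60),
           st.integers(1, 20))
    def test_matches_brute_force_trailing_mean(self, O, tau):
        O = np.array(O)
        np.testing.assert_allclose(firing_power(O, tau).fp,
                                   brute_force_fp(O, tau), rtol=1e-12)


class TestControlAlarms:
    def test_subthreshold_curve_no_alarms(self):
        c = FiringPowerCurve(np.full(100, 0.4), np.arange(100) * 5.0, tau=1)
        assert alarms_control(c, refractory_min=15).alarm_times.size == 0

    def test_single_crossing_staying_above_one_alarm(self):
        c = _step_curve(400, [100])
        alarms = alarms_control(c, refractory_min=15)
        assert alarms.alarm_times.tolist() == [500.0]

    def test_second_crossing_after_refractory_second_alarm(self):
        n = 600
        fp = np.zeros(n)
        fp[100:110] = 0.6           # crossing at t=500 s
        fp[300:310] = 0.6           # crossing at t=1500 s (> 500 + 900)
        c = FiringPowerCurve(fp, np.arange(n) * 5.0, tau=1)
        alarms = alarms_control(c, refractory_min=15)
        assert alarms.alarm_times.tolist() == [500.0, 1500.0]

    def test_crossing_inside_refractory_dropped(self):
        n = 600
        fp = np.zeros(n)
        fp[100:110] = 0.6           # t=500 s
        fp[150:160] = 0.6           # t=750 s, inside 15-min refractory
        c = FiringPowerCurve(fp, np.arange(n) * 5.0, tau=1)
        alarms = alarms_control(c, refractory_min=15)
        assert alarms.alarm_times.tolist() == [500.0]


class TestChronologicalAlarms:
    def test_ordered_occurrences_fire_at_event3(self):
        n = 720
        e1 = _step_curve(n, [int(10 * MIN / 5)])
        e2 = _step_curve(n, [int(25 * MIN / 5)])
        e3 = _step_curve(n, [int(40 * MIN / 5)])
        alarms = alarms_chronological([e1, e2, e3], span_limit_min=45,
                                      refractory_min=15)
        assert alarms.alarm_times.tolist() == [40 * MIN]

    def test_missing_event1_no_alarm(self):
        n = 720
        flat = FiringPowerCurve(np.zeros(n), np.arange(n) * 5.0, tau=1)
        e2 = _step_curve(n, [300])
        e3 = _step_curve(n, [480])
        alarms = alarms_chronological([flat, e2, e3], span_limit_min=60,
                                      refractory_min=15)
        assert alarms.alarm_times.size == 0

    def test_event2_before_event1_does_not_count(self):
        n = 720
        e1 = _step_curve(n, [300])
        e2 = _step_curve(n, [100])  # occurs before e1, never again
        e3 = _step_curve(n, [480])
        alarms = alarms_chronological([e1, e2, e3], span_limit_min=60,
                                      refractory_min=15)
        assert alarms.alarm_times.size == 0

    def test_span_limit_enforced(self):
        n = 1440
        e1 = _step_curve(n, [0])
        e2 = _step_curve(n, [10])
        e3 = _step_curve(n, [int(80 * MIN / 5)])  # 80 min after e1
        alarms = alarms_chronological([e1, e2, e3], span_limit_min=30,
                                      refractory_min=15)
        assert alarms.alarm_times.size == 0

    def test_identical_curves_reduce_to_control(self):
        rng = np.random.default_rng(0)
        O = rng.integers(0, 2, 2000)
        c = firing_power(O, tau=24, times=np.arange(2000) * 5.0)
        ctrl = alarms_control(c, refractory_min=15)
        chrono = alarms_chronological([c, c, c], span_limit_min=1e9,
                                      refractory_min=15)
        np.testing.assert_array_equal(ctrl.alarm_times, chrono.alarm_times)

    def test_unequal_lengths_rejected(self):
        a = _step_curve(100, [10])
        b = _step_curve(90, [10])
        with pytest.raises(ValueError, match="unequal"):
            alarms_chronological([a, b, b], span_limit_min=30, refractory_min=15)


def _curves_from_sum(S, times=None):
    """Three curves each S/3 so their sum is S (each within [0, 1])."""
    S = np.asarray(S, float)
    if times is None:
        times = np.arange(S.size) * 5.0
    third = FiringPowerCurve(S / 3.0, times, tau=1)
    return [third, FiringPowerCurve(S / 3.0, times, tau=1),
            FiringPowerCurve(S / 3.0, times, tau=1)]


class TestCumulativeAlarms:
    def test_sum_below_highest_threshold_no_alarm(self):
        S = np.linspace(0, 1.2, 300)
        alarms = alarms_cumulative(_curves_from_sum(S), span_limit_min=1e6,
                                   refractory_min=15)
        assert alarms.alarm_times.size == 0

    def test_monotone_rise_alarm_at_first_sample_above_1_5(self):
        S = np.linspace(0, 2, 400)
        alarms = alarms_cumulative(_curves_from_sum(S), span_limit_min=1e6,
                                   refractory_min=15)
        first = np.flatnonzero(S > 1.5)[0]
        assert alarms.alarm_times.tolist() == [first * 5.0]

    def test_single_step_jump_crosses_all_thresholds(self):
        S = np.zeros(100)
        S[40:] = 1.6
        alarms = alarms_cumulative(_curves_from_sum(S), span_limit_min=30,
                                   refractory_min=15)
        assert alarms.alarm_times.tolist() == [200.0]

    def test_span_expiry_resets_sequence(self):
        S = np.zeros(2000)
        S[0:] = 0.6           # armed at t=0
        S[1500:] = 1.6        # 1.0 and 1.5 crossed 125 min later
        alarms = alarms_cumulative(_curves_from_sum(S), span_limit_min=30,
                                   refractory_min=15)
        # the sequence expired and cannot re-arm (no new upward 0.5-crossing)
        assert alarms.alarm_times.size == 0

    def test_summed_curve_range(self):
        S = np.linspace(0, 3, 50)
        summed = sum_curves(_curves_from_sum(S))
        assert summed.range_max == 3.0
        np.testing.assert_allclose(summed.fp, S, rtol=1e-12)


class TestRefractorySpacing:
    @pytest.mark.parametrize("strategy", ["control", "chronological",
                                          "cumulative"])
    def test_alarm_spacing_on_random_curves(self, strategy):
        rng = np.random.default_rng(42)
        refr = 15.0
        for _ in range(30):
            n = 500
            times = np.arange(n) * 5.0
            fps = [np.clip(rng.random(n), 0, 1) for _ in range(3)]
            curves = [FiringPowerCurve(f, times, tau=1) for f in fps]
            if strategy == "control":
                alarms = alarms_control(curves[0], refractory_min=refr)
            elif strategy == "chronological":
                alarms = alarms_chronological(curves, span_limit_min=30,
                                              refractory_min=refr)
            else:
                scaled = [FiringPowerCurve(f / 2, times, tau=1) for f in fps]
                alarms = alarms_cumulative(scaled, span_limit_min=30,
                                           refractory_min=refr)
            gaps = np.diff(alarms.alarm_times)
            assert gaps.size == 0 or gaps.min() >= refr * MIN
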