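"""Per-phase metrics, movement-quality metrics and trial aggregation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from scapkin import (MetricSet, ScapkinError, TimeSeries,
                     aggregate_central_trials, dimensionless_jerk,
                     emg_phase_mean, log_dimensionless_jerk,
                     minimum_jerk_segment, range_of_motion,
                     scapulohumeral_rhythm, time_to_peak_percent,
                     trunk_compensation)
from scapkin.synthetic import minimum_jerk_velocity


def velocity_of(segment: TimeSeries) -> TimeSeries:
    v = np.gradient(segment.samples, 1.0 / segment.rate)
    return TimeSeries(v, segment.rate, "m/s", "v")


class TestRangeOfMotion:
    def test_constant_angle_zero_rom(self):
        angle = TimeSeries(np.full(500, 42.0), 100.0, "deg", "a")
        assert range_of_motion(angle, (0.0, 4.0)) == 0.0

    def test_full_cycle_sinusoid_gives_2a(self):
        t = np.arange(400) / 100.0
        angle = TimeSeries(7.0 * np.sin(2 * np.pi * 0.5 * t), 100.0, "deg", "a")
        assert range_of_motion(angle, (0.0, 3.99)) == pytest.approx(14.0, rel=1e-3)

    def test_sampled_ramp(self):
        angle = TimeSeries(np.linspace(3.0, 17.0, 200), 100.0, "deg", "a")
        assert range_of_motion(angle, (0.0, 1.99)) == pytest.approx(14.0)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(offset=st.floats(-500, 500))
    def test_offset_invariance(self, offset):
        base = np.sin(np.linspace(0, 7, 300))
        a = TimeSeries(base, 100.0, "deg", "a")
        b = TimeSeries(base + offset, 100.0, "deg", "b")
        assert range_of_motion(a, (0, 2.99)) == pytest.approx(
            range_of_motion(b, (0, 2.99)), abs=1e-9)

    def test_empty_window_rejected(self):
        angle = TimeSeries(np.zeros(100), 100.0, "deg", "a")
        with pytest.raises(ScapkinError):
            range_of_motion(angle, (0.9, 0.1))


class TestScapulohumeralRhythm:
    def test_ratio_of_roms(self):
        t = np.linspace(0, 1, 101)
        elev = TimeSeries(90.0 * t, 100.0, "deg", "elev")
        ur = TimeSeries(30.0 * t, 100.0, "deg", "ur")
        assert scapulohumeral_rhythm(elev, ur, (0.0, 1.0)) == pytest.approx(3.0)

    def test_degenerate_denominator(self):
        t = np.linspace(0, 1, 101)
        elev = TimeSeries(90.0 * t, 100.0, "deg", "elev")
        ur = TimeSeries(0.1 * t, 100.0, "deg", "ur")
        with pytest.raises(ScapkinError, match="degeneracy"):
            scapulohumeral_rhythm(elev, ur, (0.0, 1.0))


class TestDimensionlessJerk:
    def test_minimum_jerk_closed_form_102_4(self):
        # (D^3 / v_peak^2) * (1/2) int j^2 = 360 / 1.875^2 -> 102.4
        seg = minimum_jerk_segment(0.45, 1.2, 2000.0)
        v = velocity_of(seg)
        dj = dimensionless_jerk(v, (0.0, v.duration - 1e-9))
        assert dj == pytest.approx(102.4, rel=5e-3)
        assert log_dimensionless_jerk(v, (0.0, v.duration - 1e-9)) == \
            pytest.approx(np.log(102.4), abs=5e-3)

    def test_amplitude_variant_jerk_cost_360(self):
        # (D^5 / A^2) * (1/2) int j^2 = 360 for a minimum-jerk segment
        seg = minimum_jerk_segment(0.3, 0.8, 2000.0)
        v = velocity_of(seg)
        dj = dimensionless_jerk(v, (0.0, v.duration - 1e-9), variant="amplitude")
        assert dj == pytest.approx(360.0, rel=5e-3)

    @pytest.mark.parametrize("duration", [0.5, 1.0, 2.5])
    @pytest.mark.parametrize("amp", [0.1, 0.45, 2.0])
    def test_time_and_amplitude_rescale_invariance(self, duration, amp):
        seg = minimum_jerk_segment(amp, duration, 2000.0)
        v = velocity_of(seg)
        dj = dimensionless_jerk(v, (0.0, v.duration - 1e-9))
        assert dj == pytest.approx(102.4, rel=5e-3)

    def test_velocity_subpeaks_strictly_increase_jerk(self):
        rate = 2000.0
        tau = np.arange(int(1.0 * rate) + 1) / (1.0 * rate)
        base = minimum_jerk_velocity(tau, 0.45, 1.0)
        wiggle = 0.05 * np.sin(np.pi * tau) ** 2 * np.sin(2 * np.pi * 3 * tau)
        v0 = TimeSeries(base, rate, "m/s", "v")
        v1 = TimeSeries(base + np.gradient(wiggle, 1 / rate) * 0.02, rate,
                        "m/s", "v")
        win = (0.0, v0.duration - 1e-9)
        assert dimensionless_jerk(v1, win) > dimensionless_jerk(v0, win)

    def test_zero_peak_speed_rejected(self):
        v = TimeSeries(np.zeros(1000), 2000.0, "m/s", "v")
        with pytest.raises(ScapkinError):
            dimensionless_jerk(v, (0.0, 0.4))

    def test_unknown_variant_rejected(self):
        v = velocity_of(minimum_jerk_segment(0.3, 1.0, 2000.0))
        with pytest.raises(ScapkinError, match="variant"):
            dimensionless_jerk(v, (0.0, 0.9), variant="banana")


class TestTimeToPeakPercent:
    def test_minimum_jerk_peak_location(self):
        # |a| peaks at tau = (3 - sqrt(3))/6 of the reaching segment
        rate = 2000.0
        d_reach, d_task = 1.0, 5.0
        seg = minimum_jerk_segment(0.45, d_reach, rate)
        a = np.gradient(np.gradient(seg.samples, 1 / rate), 1 / rate)
        accel = TimeSeries(np.concatenate([a, np.zeros(int((d_task - d_reach)
                                                           * rate))]),
                           rate, "m/s^2", "a")
        pct = time_to_peak_percent(accel, (0.0, d_reach), (0.0, d_task))
        tau = (3 - np.sqrt(3)) / 6
        assert pct == pytest.approx(100 * tau * d_reach / d_task, abs=0.2)

    def test_constant_acceleration_earliest_tie(self):
        accel = TimeSeries(np.full(1000, 2.0), 2000.0, "m/s^2", "a")
        pct = time_to_peak_percent(accel, (0.1, 0.3), (0.0, 0.49))
        assert pct == pytest.approx(100 * 0.1 / 0.49, rel=1e-6)

    def test_bounded_zero_to_hundred(self, rng):
        for _ in range(50):
            a = TimeSeries(rng.normal(size=2000), 2000.0, "m/s^2", "a")
            pct = time_to_peak_percent(a, (0.2, 0.5), (0.0, 0.999))
            assert 0.0 <= pct <= 100.0


class TestTrunkCompensation:
    def test_constant_at_neutral(self):
        a = TimeSeries(np.full(600, 4.0), 100.0, "deg", "t")
        assert trunk_compensation(a, (0.0, 5.99), neutral=4.0) == 0.0

    def test_signed_max_abs_rule(self):
        x = np.zeros(600)
        x[100] = 2.0
        x[200] = -5.0
        a = TimeSeries(x, 100.0, "deg", "t")
        assert trunk_compensation(a, (0.0, 5.99), neutral=0.0) == -5.0


class TestEmgPhaseMean:
    def test_constant_envelope(self):
        e = TimeSeries(np.full(500, 40.0), 100.0, "%SVIC", "e")
        assert emg_phase_mean(e, (0.0, 4.99)) == pytest.approx(40.0)

    def test_step_across_equal_halves(self):
        e = TimeSeries(np.concatenate([np.full(100, 20.0), np.full(100, 60.0)]),
                       100.0, "%SVIC", "e")
        assert emg_phase_mean(e, (0.0, 1.99)) == pytest.approx(40.0)


class TestAggregateCentralTrials:
    @staticmethod
    def _sets(values):
        return [MetricSet({"m": float(v)}) for v in values]

    def test_mean_of_trials_2_to_4(self):
        agg = aggregate_central_trials(self._sets([1, 2, 3, 4, 5]))
        assert agg["m"] == 3.0

    def test_identical_trials_pass_through(self):
        agg = aggregate_central_trials(self._sets([7, 7, 7, 7, 7]))
        assert agg["m"] == 7.0

    def test_edge_trials_do_not_matter_central_do(self):
        base = [1, 2, 3, 4, 5]
        swapped_edges = [5, 2, 3, 4, 1]
        swapped_central = [1, 5, 3, 4, 2]
        assert aggregate_central_trials(self._sets(swapped_edges))["m"] == \
            aggregate_central_trials(self._sets(base))["m"]
        assert aggregate_central_trials(self._sets(swapped_central))["m"] != \
            aggregate_central_trials(self._sets(base))["m"]

    def test_wrong_count_rejected_by_default(self):
        with pytest.raises(ScapkinError, match="5 trials"):
            aggregate_central_trials(self._sets([1, 2, 3]))

    def test_wrong_count_fallback_mean(self):
        agg = aggregate_central_trials(self._sets([1, 2, 3]),
                                       on_count_mismatch="mean")
        assert agg["m"] == 2.0
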