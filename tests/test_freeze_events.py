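import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import icekin as ik
from icekin.freeze_events import DeltaSeries, detect_events


class TestFitChilling:
    def test_exact_line_closed_form(self, linear_curve):
        line = ik.fit_chilling(linear_curve)
        assert line.cl_rate == pytest.approx(-16.0, abs=1e-9)
        assert line.intercept == pytest.approx(20.0, abs=1e-9)
        assert line.tp1 == pytest.approx(1.25, abs=1 / 60)

    def test_noisy_generator_slope_recovered(self):
        scenario = ik.CurveScenario(cl_rate=-17.69, t0=22.11)
        curve, truth = ik.generate_cooling_curve(scenario, seed=7)
        line = ik.fit_chilling(ik.smooth_sg3(curve))
        assert line.cl_rate == pytest.approx(truth.cl_rate, abs=0.5)

    def test_all_subzero_curve_rejected(self):
        t = np.arange(0.0, 2.0, 1 / 60)
        with pytest.raises(ik.DetectionError):
            ik.fit_chilling(ik.CoolingCurve(t, -1.0 - t))

    def test_never_crossing_curve_rejected(self):
        t = np.arange(0.0, 2.0, 1 / 60)
        with pytest.raises(ik.DetectionError):
            ik.fit_chilling(ik.CoolingCurve(t, 20.0 - t))


class TestDeltaFunction:
    def test_zero_on_the_chilling_line(self, linear_curve):
        line = ik.fit_chilling(linear_curve)
        d = ik.delta_function(linear_curve, line)
        np.testing.assert_allclose(d.delta, 0.0, atol=1e-18)

    def test_direct_arithmetic(self):
        # T_CL = -4, T_exp = -2 -> delta = (-4 + 2)^2 / 2 = 2
        t = np.arange(0.0, 2.0001, 1 / 60)
        T = 20.0 - 16.0 * t
        T[-1] = -2.0
        curve = ik.CoolingCurve(t, T)
        line = ik.ChillingLine(-16.0, 20.0, (0.0, 1.25), 1.25)
        d = ik.delta_function(curve, line)
        t_cl = 20.0 - 16.0 * t[-1]
        assert t_cl == pytest.approx(-12.0)
        assert d.delta[-1] == pytest.approx((t_cl + 2.0) ** 2 / 2.0)

    def test_epsilon_guard_near_zero_temperature(self):
        t = np.arange(0.0, 2.0001, 1 / 60)
        T = 20.0 - 16.0 * t
        T[t > 1.25] = -0.01  # |T_exp| below the guard
        curve = ik.CoolingCurve(t, T)
        line = ik.ChillingLine(-16.0, 20.0, (0.0, 1.25), 1.25)
        d = ik.delta_function(curve, line, eps=0.5)
        dev = (20.0 - 16.0 * t[t > 1.25]) + 0.01
        np.testing.assert_allclose(d.delta, dev**2 / 0.5)

    def test_rapid_growth_at_supercooling_onset(self, noisefree_run):
        curve, truth = noisefree_run
        work = ik.smooth_sg3(curve)
        line = ik.fit_chilling(work)
        d = ik.delta_function(work, line)
        onset = d.time[np.nonzero(d.delta > d.threshold)[0][0]]
        assert onset < truth.s_time  # departure precedes the dip minimum
        assert onset > truth.tp1


class TestSupercoolingDetection:
    def test_linear_curve_has_no_event(self, linear_curve):
        line = ik.fit_chilling(linear_curve)
        d = ik.delta_function(linear_curve, line)
        with pytest.raises(ik.DetectionError):
            ik.detect_first_supercooling(linear_curve, d)

    def test_single_dip_location(self, default_run):
        # the dip bottom is flat, so the time of the noisy minimum carries an
        # intrinsic scatter ~ sqrt(noise/curvature) of a few tenths of a minute
        curve, truth = default_run
        ev = detect_events(curve)
        assert ev.s_time == pytest.approx(truth.s_time, abs=0.3)
        assert ev.s_temp == pytest.approx(truth.s_temp, abs=0.2)
        assert ev.supercooling_count >= 1

    def test_single_dip_exact_on_noise_free_curve(self, noisefree_run):
        curve, truth = noisefree_run
        ev = detect_events(curve)
        assert ev.s_time == pytest.approx(truth.s_time, abs=1 / 60)
        assert ev.s_temp == pytest.approx(truth.s_temp, abs=0.02)
        assert ev.supercooling_count == 1

    def test_two_dips_counted_first_is_initial(self):
        scenario = ik.CurveScenario(
            events=(ik.SupercoolEvent(2.5, -2.8), ik.SupercoolEvent(3.4, -2.6, width=0.25))
        )
        curve, truth = ik.generate_cooling_curve(scenario, seed=3)
        ev = detect_events(curve)
        assert ev.supercooling_count == 2
        assert ev.s_time == pytest.approx(2.5, abs=0.1)

    def test_monotone_decline_rejected(self):
        scenario = ik.CurveScenario(events=(), noise_sigma=0.0)
        curve, _ = ik.generate_cooling_curve(scenario)
        with pytest.raises(ik.DetectionError, match="no supercooling"):
            detect_events(curve)


class TestLocateIFP:
    def test_exact_line_time_intercept(self):
        # delta values on the exact line 5 (t - 3): intercept at t = 3
        t = np.linspace(3.05, 6.0, 60)
        d = DeltaSeries(t, 5.0 * (t - 3.0), threshold=10.0)
        tt = np.arange(0.0, 6.0001, 1 / 60)
        # continuous anatomy: chilling to 0 degC at 1.25, descent to the dip
        # (2.0, -2.8), rebound to -2.2 at 2.6, then a gentle hump
        T = np.piecewise(
            tt,
            [tt <= 1.25, (tt > 1.25) & (tt <= 2.0), (tt > 2.0) & (tt <= 2.6), tt > 2.6],
            [
                lambda x: 20 - 16 * x,
                lambda x: -2.8 * (x - 1.25) / 0.75,
                lambda x: -2.8 + (x - 2.0),
                lambda x: -2.2 + 0.01 * (x - 2.6),
            ],
        )
        curve = ik.CoolingCurve(tt, T)
        t_ifp, T_ifp, method = ik.locate_ifp(curve, d, s_time=2.0, min_span=0.5)
        assert method == "delta-regression"
        a, b = np.polyfit(t[np.argsort(d.delta)[-10:]], np.sort(d.delta)[-10:], 1)
        assert -b / a == pytest.approx(3.0, abs=1e-9)
        assert T_ifp == pytest.approx(-2.2, abs=0.05)

    def test_plateau_recovered_on_synthetic(self, default_run):
        curve, truth = default_run
        ev = detect_events(curve)
        assert ev.ifp_temp == pytest.approx(truth.ifp_temp, abs=0.2)
        assert ev.ifp_time > ev.s_time

    def test_no_rebound_degenerates_to_supercooling_point(self):
        t = np.arange(0.0, 3.0001, 1 / 60)
        T = np.where(t <= 1.25, 20 - 16 * t, 0.0)
        seg = t > 1.25
        T[seg] = -2.8 * np.clip((t[seg] - 1.25) / 1.25, 0, 1)  # descend and stay
        curve = ik.CoolingCurve(t, T)
        line = ik.fit_chilling(curve)
        d = ik.delta_function(curve, line)
        t_ifp, T_ifp, method = ik.locate_ifp(curve, d, s_time=float(t[-1]))
        assert method == "degenerate-S"
        assert t_ifp == pytest.approx(t[-1], abs=1e-6)


class TestNucleationMetrics:
    def test_exact_segment_slope(self):
        t = np.arange(0.0, 3.0001, 1 / 60)
        T = np.where(t <= 1.0, 20 - 20 * t, -0.49 * (t - 1.0))
        curve = ik.CoolingCurve(t, T)
        nur, hnt = ik.nucleation_metrics(curve, tp1=1.0, s_time=2.5, ifp_time=2.8)
        assert nur == pytest.approx(-0.49, abs=1e-9)
        assert hnt == pytest.approx(1.8)

    def test_ordering_violation_rejected(self, linear_curve):
        with pytest.raises(ik.ValidationError):
            ik.nucleation_metrics(linear_curve, tp1=1.5, s_time=1.0, ifp_time=2.0)

    def test_closed_loop_hnt(self, default_run):
        curve, truth = default_run
        ev = detect_events(curve)
        truth_hnt = truth.ifp_time - truth.tp1
        assert ev.hnt == pytest.approx(truth_hnt, abs=0.5)


class TestCalibration:
    def test_identity_when_ifp_equals_fpt(self, linear_curve):
        cal, offset = ik.calibrate(linear_curve, -2.9, -2.9)
        assert offset == 0.0
        np.testing.assert_array_equal(cal.temperature, linear_curve.temperature)

    def test_printed_offset_example(self, linear_curve):
        _, offset = ik.calibrate(linear_curve, -2.12, -3.71)
        assert offset == pytest.approx(1.59, abs=1e-9)

    @given(ifp=st.floats(-5.0, -0.5), fpt=st.floats(-8.0, -0.5))
    @settings(max_examples=50, deadline=None)
    def test_postcondition_calibrated_ifp_equals_fpt(self, ifp, fpt):
        t = np.arange(0.0, 2.0001, 1 / 60)
        curve = ik.CoolingCurve(t, 20.0 - 16.0 * t)
        cal, offset = ik.calibrate(curve, ifp, fpt)
        assert ifp - offset == pytest.approx(fpt, abs=1e-12, rel=1e-12)
        # pure shift: intervals and temperature differences preserved
        np.testing.assert_allclose(
            np.diff(cal.temperature), np.diff(curve.temperature), atol=1e-12
        )

    def test_negative_offset_warns_not_raises(self, linear_curve):
        with pytest.warns(UserWarning):
            _, offset = ik.calibrate(linear_curve, -3.0, -2.0)
        assert offset == -1.0


class TestEventOrderingInvariant:
    @pytest.mark.parametrize("seed", range(0, 40))
    def test_tp1_before_s_before_ifp(self, seed):
        curve, _ = ik.generate_cooling_curve(seed=seed)
        ev = detect_events(curve)
        assert ev.tp1 < ev.s_time < ev.ifp_time
        assert ev.hnt > 0
        assert ev.nur < 0


class TestLabelSegments:
    def test_six_contiguous_phases_on_full_curve(self, default_run):
        curve, truth = default_run
        ev = detect_events(curve)
        labels = ik.label_segments(curve, ev, ifp_eff_time=truth.ifp_eff_time)
        seen = [labels[0]]
        for lab in labels[1:]:
            if lab != seen[-1]:
                seen.append(lab)
        assert seen == [
            "chilling",
            "dynamic_nucleation",
            "ifp",
            "steady_state",
            "ifp_eff",
            "dynamic_ice_crystallization",
        ]

    def test_labels_partition_time_axis(self, default_run):
        curve, truth = default_run
        ev = detect_events(curve)
        labels = ik.label_segments(curve, ev, ifp_eff_time=truth.ifp_eff_time)
        assert all(lab is not None for lab in labels)
        assert len(labels) == len(curve)

    def test_truncated_curve_partial_labels(self, default_run):
        curve, _ = default_run
        ev = detect_events(curve)
        with pytest.warns(UserWarning):
            labels = ik.label_segments(curve, ev, ifp_eff_time=None)
        assert "ifp_eff" not in set(labels)
        assert "dynamic_ice_crystallization" not in set(labels)
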