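"""Spring-mass leg stiffness and heel-marker timing."""

import numpy as np
import pytest

from stridepower.grf_pipeline import G, ValidationError, detect_contacts
from stridepower.stiffness_kinematics import (
    MarkerTrace,
    detect_heel_strikes,
    flight_time,
    leg_stiffness,
    stride_time,
    vertical_com_displacement,
)


class TestVerticalDisplacement:
    def test_zero_acceleration_zero_entry_gives_zero(self):
        assert vertical_com_displacement(np.zeros(100), 0.002, 0.0) == 0.0

    def test_free_fall_closed_form(self):
        # constant Az = -g from rest over T: dy = g T^2 / 2
        T, dt = 0.3, 0.0005
        az = np.full(int(T / dt) + 1, -G)
        dy = vertical_com_displacement(az, dt, 0.0)
        assert dy == pytest.approx(0.5 * G * T**2, rel=2e-3)

    def test_window_too_short_rejected(self):
        with pytest.raises(ValidationError):
            vertical_com_displacement(np.zeros(2), 0.002, 0.0)


class TestLegStiffness:
    def test_stationary_limit_is_pure_vertical_spring(self):
        res = leg_stiffness(2000.0, 0.05, 0.0, 0.25, 0.95)
        assert res.theta == 0.0
        assert res.kleg == pytest.approx(40.0)

    def test_hand_computed_geometry(self):
        res = leg_stiffness(2000.0, 0.04, 4.0, 0.25, 0.95)
        assert res.theta == pytest.approx(0.5546, abs=1e-3)
        assert res.dl == pytest.approx(0.1822, abs=2e-4)
        assert res.kleg == pytest.approx(10.98, abs=0.02)

    def test_literal_theta_compatibility_mode(self):
        lit = leg_stiffness(2000.0, 0.04, 4.0, 0.25, 0.95, literal_theta=True)
        assert lit.theta == pytest.approx(4.0 * 0.25 / (2 * 0.95))
        assert lit.kleg > 0

    def test_monotone_decreasing_in_dy_and_tc(self):
        klegs_dy = [leg_stiffness(2000.0, dy, 4.0, 0.25, 0.95).kleg
                    for dy in np.linspace(0.02, 0.10, 7)]
        assert np.all(np.diff(klegs_dy) < 0)
        klegs_tc = [leg_stiffness(2000.0, 0.04, 4.0, tc, 0.95).kleg
                    for tc in np.linspace(0.18, 0.32, 7)]
        assert np.all(np.diff(klegs_tc) < 0)

    def test_non_physical_sweep_rejected(self):
        with pytest.raises(ValidationError):
            leg_stiffness(2000.0, 0.04, 9.0, 0.25, 0.95)


class TestStrideTime:
    def test_two_strikes_hand_value(self):
        ts, omega = stride_time(np.array([10.00, 10.70]))
        assert ts == pytest.approx(0.35)
        assert omega == pytest.approx(2.857, abs=1e-3)

    def test_scaling(self):
        ts1, w1 = stride_time(np.array([0.0, 0.7]))
        ts2, w2 = stride_time(np.array([0.0, 1.4]))
        assert ts2 == pytest.approx(2 * ts1)
        assert w2 == pytest.approx(w1 / 2)

    def test_multiple_strikes_average(self):
        ts, _ = stride_time(np.array([0.0, 0.7, 1.4, 2.1]))
        assert ts == pytest.approx(0.35)

    def test_errors(self):
        with pytest.raises(ValidationError):
            stride_time(np.array([1.0]))
        with pytest.raises(ValidationError):
            stride_time(np.array([1.0, 0.5]))


class TestHeelStrikes:
    def _marker(self, strikes, period=0.7, rate=400.0, swing=0.12):
        dt = 1.0 / rate
        t = np.arange(0.0, strikes[-1] + period, dt)
        z = np.full_like(t, 0.02)
        for s0, s1 in zip(strikes, list(strikes[1:]) + [strikes[-1] + period]):
            m = (t > s0 + 0.25) & (t < s1)
            z[m] += swing * np.sin(np.pi * (t[m] - s0 - 0.25) / (s1 - s0 - 0.25)) ** 2
        return MarkerTrace(t=t, z=z)

    def test_strikes_found_near_construction_times(self):
        # the first strike sits inside the opening flat plateau and is
        # inherently undatable; all later strikes are sharp plateau edges
        strikes = np.array([0.5, 1.2, 1.9, 2.6])
        marker = self._marker(strikes)
        found = detect_heel_strikes(marker, stride_period_hint=0.7)
        assert len(found) >= len(strikes) - 1
        for s in strikes[1:]:
            assert np.min(np.abs(found - s)) <= 0.005

    def test_constant_height_yields_nothing(self):
        t = np.arange(0, 2, 0.0025)
        marker = MarkerTrace(t=t, z=np.full_like(t, 0.05))
        assert detect_heel_strikes(marker).size == 0

    def test_flight_time_intervals(self):
        strikes = np.array([0.5, 1.2, 1.9, 2.6])
        marker = self._marker(strikes)
        tf = flight_time(marker)
        assert tf.size >= 2
        # swing lasts period - contact = 0.45 s by construction
        assert np.median(tf) == pytest.approx(0.45, abs=0.06)


class TestCrossInstrumentConsistency:
    def test_marker_strikes_agree_with_platform_contacts(self, noiseless_session):
        """Heel-strike times from the optical marker match the force-plate
        strike times of the instrumented foot within 5 ms."""
        s = noiseless_session
        trace = s.force_traces[1]
        contacts = detect_contacts(trace)
        left_steps = s.truth[s.truth["foot"] == 0]
        sel = (s.marker.t >= trace.t[0] - 0.3) & (s.marker.t <= trace.t[-1] + 0.3)
        marker = MarkerTrace(t=s.marker.t[sel], z=s.marker.z[sel])
        found = detect_heel_strikes(marker, stride_period_hint=0.7)
        matched = 0
        for c in contacts:
            near_left = np.min(np.abs(left_steps["t"].to_numpy() - c.strike_time))
            if near_left > 0.01:
                continue  # contralateral foot: not on the marker
            if found.size and np.min(np.abs(found - c.strike_time)) <= 0.005:
                matched += 1
        assert matched >= 1
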