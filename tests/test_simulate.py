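"""Synthetic-session generator: closed-form mechanics and determinism."""

import numpy as np
import pandas as pd
import pytest
from pandas.testing import assert_frame_equal

from stridepower.grf_pipeline import G, ValidationError
from stridepower.simulate import (
    DeviceBiasModel,
    GaitModel,
    ProtocolConfig,
    SubjectProfile,
    apply_device_bias,
    peak_force,
    simulate_session,
    simulate_vo2,
    solve_contact_time,
    spring_mass_stride,
    stage_speeds,
)


class TestSpringMassStride:
    def test_peak_force_impulse_balance_formula(self, subject):
        # m g (pi/2) (T/Tc) for m=70, T=0.7, Tc=0.25
        assert peak_force(70.0, 0.7, 0.25) == pytest.approx(3019.23, abs=0.5)

    def test_emitted_impulse_equals_body_weight_times_period(self, subject):
        trace, truth = spring_mass_stride(4.0, subject, 10.0, 0.32)
        impulse = np.trapezoid(trace.fz, trace.t)
        expected = subject.mass * G * truth.t_stride
        assert impulse == pytest.approx(expected, rel=1e-3)

    def test_horizontal_impulse_is_zero(self, subject):
        trace, truth = spring_mass_stride(4.0, subject, 10.0, 0.32)
        net = np.trapezoid(trace.fx, trace.t)
        braking = np.trapezoid(np.minimum(trace.fx, 0.0), trace.t)
        assert abs(net) < 0.01 * abs(braking)

    def test_truth_kleg_matches_requested_value(self, subject):
        for kleg in (8.0, 10.0, 12.0):
            _, truth = spring_mass_stride(3.5, subject, kleg, 0.34)
            assert truth.kleg == pytest.approx(kleg, rel=1e-8)

    def test_contact_time_solution_decreases_with_speed(self, subject):
        tcs = [solve_contact_time(v, subject, 10.0, GaitModel().duty_factor(v))
               for v in (2.5, 3.5, 4.5)]
        assert tcs[0] > tcs[1] > tcs[2]

    @pytest.mark.parametrize("speed,duty", [(-1.0, 0.3), (4.0, 1.2), (4.0, 0.0)])
    def test_non_physical_inputs_rejected(self, subject, speed, duty):
        with pytest.raises(ValidationError):
            spring_mass_stride(speed, subject, 10.0, duty)


class TestSessionProtocol:
    def test_stage_speeds_arithmetic_progression(self):
        sub = SubjectProfile(mass=70, height=1.75, initial_speed_kmh=10.0)
        speeds = stage_speeds(sub, ProtocolConfig(max_speed_kmh=12.0))
        assert np.allclose(speeds, [10.0, 10.5, 11.0, 11.5, 12.0])

    def test_zero_stages_is_an_error(self):
        sub = SubjectProfile(mass=70, height=1.75, initial_speed_kmh=20.0)
        with pytest.raises(ValidationError):
            stage_speeds(sub, ProtocolConfig(max_speed_kmh=19.0))

    def test_same_seed_identical_output(self, subject, short_protocol):
        a = simulate_session(subject, short_protocol, DeviceBiasModel.underreading(), seed=5)
        b = simulate_session(subject, short_protocol, DeviceBiasModel.underreading(), seed=5)
        assert_frame_equal(a.pod, b.pod)
        assert_frame_equal(a.truth, b.truth)
        assert_frame_equal(a.breaths, b.breaths)
        for lap in a.force_traces:
            assert np.array_equal(a.force_traces[lap].fz, b.force_traces[lap].fz)

    def test_streams_share_time_origin_and_platforms_each_lap(self, noiseless_session):
        s = noiseless_session
        assert s.pod["t"].iloc[0] == 0.0
        assert s.marker.t[0] == 0.0
        # every lap the runner completed has a platform passage
        n_laps = int(s.truth["pos"].iloc[-1] // s.protocol.lap_length)
        assert set(range(n_laps)) <= set(s.force_traces)

    def test_mean_vertical_force_is_body_weight(self, noiseless_session):
        # impulse balance over whole strides, within 0.5%
        s = noiseless_session
        trace = s.force_traces[1]
        steps = s.truth[(s.truth.t >= trace.t[0]) & (s.truth.t <= trace.t[-1])]
        t0 = steps["t"].iloc[0]
        t1 = steps["t"].iloc[-1]  # whole number of cycles between strikes
        sel = (trace.t >= t0) & (trace.t < t1)
        mean_force = np.trapezoid(trace.fz[sel], trace.t[sel]) / (t1 - t0)
        assert mean_force == pytest.approx(s.subject.mass * G, rel=5e-3)


class TestDeviceBias:
    def _truth(self, n=100, power=600.0):
        return pd.DataFrame(
            {
                "t": np.arange(n, dtype=float),
                "speed": np.full(n, 4.0),
                "power": np.full(n, power),
                "gct_s": np.full(n, 0.25),
                "lss": np.full(n, 10.0),
                "distance": np.arange(n, dtype=float) * 4.0,
            }
        )

    def test_constant_offset(self):
        bias = DeviceBiasModel(po_offset_w=-300.0)
        pod = apply_device_bias(self._truth(), bias)
        assert np.allclose(pod["power"], 300.0)

    def test_identity_bias_reproduces_truth(self):
        pod = apply_device_bias(self._truth(), DeviceBiasModel())
        assert np.allclose(pod["power"], 600.0)
        assert np.allclose(pod["gct_ms"], 250.0)
        assert np.allclose(pod["lss"], 10.0)

    def test_noisy_offset_sample_mean(self):
        # offset -300, sd 20, n=100: mean within +-6 W (3 standard errors)
        bias = DeviceBiasModel(po_offset_w=-300.0, noise_sd_po=20.0)
        pod = apply_device_bias(self._truth(), bias, np.random.default_rng(42))
        assert (pod["power"] - 600.0).mean() == pytest.approx(-300.0, abs=6.0)

    def test_speed_proportional_term(self):
        bias = DeviceBiasModel(po_slope_w_per_mps=-20.0)
        pod = apply_device_bias(self._truth(), bias)
        assert np.allclose(pod["power"], 600.0 - 80.0)

    def test_empty_truth_rejected(self):
        with pytest.raises(ValidationError):
            apply_device_bias(self._truth(0), DeviceBiasModel())


class TestVo2Simulator:
    def test_first_order_response_at_tau(self, subject):
        # noiseless: at t = tau after a step, 63.2% of the amplitude
        t = np.arange(0.0, 601.0)
        power = np.where(t < 300, 0.0, 500.0)
        rng = np.random.default_rng(0)
        out = simulate_vo2(t, power, subject, tau=30.0, noise_sd=0.0, rng=rng)
        vo2 = np.interp([299.0, 330.0, 600.0], out["t"], out["vo2"])
        amplitude = vo2[2] - vo2[0]
        completed = (vo2[1] - vo2[0]) / amplitude
        assert completed == pytest.approx(1 - np.exp(-1), abs=0.05)

    def test_zero_power_stays_at_rest(self, subject):
        t = np.arange(0.0, 120.0)
        out = simulate_vo2(t, np.zeros_like(t), subject, noise_sd=0.0,
                           rng=np.random.default_rng(1))
        assert np.allclose(out["vo2"], subject.vo2_rest, atol=1e-9)

    def test_steady_state_saturates_at_vo2max(self, subject):
        t = np.arange(0.0, 1200.0)
        out = simulate_vo2(t, np.full_like(t, 5000.0), subject, tau=5.0,
                           noise_sd=0.0, rng=np.random.default_rng(2))
        assert out["vo2"].max() <= subject.vo2max + 1e-9

    def test_empty_profile_rejected(self, subject):
        with pytest.raises(ValidationError):
            simulate_vo2(np.array([]), np.array([]), subject)

    def test_breath_intervals_shrink_with_intensity(self, subject):
        t = np.arange(0.0, 1200.0)
        power = np.where(t < 600, 0.0, 600.0)
        out = simulate_vo2(t, power, subject, tau=5.0, noise_sd=0.0,
                           rng=np.random.default_rng(3))
        early = np.diff(out["t"][out["t"] < 500])
        late = np.diff(out["t"][out["t"] > 700])
        assert late.mean() < early.mean()
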