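"""Force-platform kinetics: contact detection, integration, works, power."""

import numpy as np
import pytest

from stridepower.grf_pipeline import (
    G,
    DEFAULT_THRESHOLD,
    ForceTrace,
    ValidationError,
    decompose_acceleration,
    detect_contacts,
    external_power,
    integrate_motion,
    mechanical_cost,
    stride_work,
)


def half_sine_trace(durations, gaps, peak=1500.0, rate=500.0, mass=70.0, t0=0.0):
    """Concatenated half-sine contacts separated by flight gaps."""
    dt = 1.0 / rate
    total = sum(durations) + sum(gaps) + 0.1
    t = t0 + np.arange(int(total * rate)) * dt
    fz = np.zeros_like(t)
    start = t0 + 0.02
    for dur, gap in zip(durations, list(gaps) + [0.0]):
        rel = t - start
        m = (rel >= 0) & (rel < dur)
        fz[m] = peak * np.sin(np.pi * rel[m] / dur)
        start += dur + gap
    return ForceTrace(t=t, fz=fz, fx=np.zeros_like(t), mass=mass)


class TestDetectContacts:
    def test_single_contact_duration_within_two_samples(self):
        trace = half_sine_trace([0.250], [])
        events = detect_contacts(trace, threshold=20.0)
        assert len(events) == 1
        assert events[0].gct == pytest.approx(0.250, abs=0.004)

    def test_silent_trace_yields_no_events(self):
        t = np.arange(500) * 0.002
        trace = ForceTrace(t=t, fz=np.zeros_like(t), fx=np.zeros_like(t), mass=70.0)
        assert detect_contacts(trace) == []

    def test_two_contacts_with_flight(self):
        trace = half_sine_trace([0.25, 0.22], [0.10])
        events = detect_contacts(trace)
        assert len(events) == 2
        assert events[0].gct == pytest.approx(0.25, abs=0.004)
        assert events[1].gct == pytest.approx(0.22, abs=0.004)
        assert events[0].toe_off_time <= events[1].strike_time

    def test_debounce_discards_spikes(self):
        trace = half_sine_trace([0.004], [])
        assert detect_contacts(trace, debounce_s=0.010) == []

    def test_raising_threshold_never_lengthens_gct(self):
        trace = half_sine_trace([0.25, 0.22], [0.10])
        lo = detect_contacts(trace, threshold=20.0)
        hi = detect_contacts(trace, threshold=100.0)
        for a, b in zip(lo, hi):
            assert b.gct <= a.gct + 1e-12

    def test_time_shift_invariance(self):
        a = detect_contacts(half_sine_trace([0.25], [], t0=0.0))
        b = detect_contacts(half_sine_trace([0.25], [], t0=37.0))
        assert a[0].gct == pytest.approx(b[0].gct, abs=1e-12)
        assert b[0].strike_time - a[0].strike_time == pytest.approx(37.0, abs=1e-9)

    def test_non_uniform_sampling_rejected(self):
        t = np.r_[np.arange(100) * 0.002, 0.3]
        with pytest.raises(ValidationError):
            ForceTrace(t=t, fz=np.zeros_like(t), fx=np.zeros_like(t), mass=70.0)


class TestDecomposeAcceleration:
    def test_weight_support_gives_zero(self):
        t = np.arange(10) * 0.002
        trace = ForceTrace(t=t, fz=np.full_like(t, 70 * G), fx=np.zeros_like(t),
                           mass=70.0)
        az, ax = decompose_acceleration(trace)
        assert np.allclose(az, 0.0) and np.allclose(ax, 0.0)

    def test_double_body_weight_gives_g(self):
        t = np.arange(10) * 0.002
        trace = ForceTrace(t=t, fz=np.full_like(t, 2 * 70 * G), fx=np.zeros_like(t),
                           mass=70.0)
        az, _ = decompose_acceleration(trace)
        assert np.allclose(az, G)

    def test_hand_computed_value(self):
        t = np.arange(10) * 0.002
        trace = ForceTrace(t=t, fz=np.full_like(t, 1500.0), fx=np.zeros_like(t),
                           mass=70.0)
        az, _ = decompose_acceleration(trace)
        assert az[0] == pytest.approx((1500 - 70 * G) / 70, abs=1e-6)
        assert az[0] == pytest.approx(11.622, abs=1e-3)


class TestIntegrateMotion:
    def test_constant_motion(self):
        n, dt = 500, 0.002
        sz, sx, dz, dx = integrate_motion(np.zeros(n), np.zeros(n), dt, 3.0)
        assert np.allclose(sx, 3.0)
        assert dx[-1] == pytest.approx(3.0 * (n - 1) * dt, rel=1e-9)
        assert np.allclose(sz, 0.0)

    def test_sinusoid_matches_closed_form(self):
        # Az = A sin(w t): Sz = -A/w cos(w t) + c, zero-mean over whole periods
        dt, f, amp = 0.002, 2.0, 5.0
        t = np.arange(0, 2.0, dt)  # four whole periods
        w = 2 * np.pi * f
        sz, _, dz, _ = integrate_motion(amp * np.sin(w * t), np.zeros_like(t), dt, 0.0)
        exact = -amp / w * np.cos(w * t)
        assert np.max(np.abs(sz - exact)) < 1e-3 * amp / w

    def test_stride_mean_vertical_velocity_is_zero(self):
        rng = np.random.default_rng(0)
        az = rng.normal(size=400)
        sz, *_ = integrate_motion(az, np.zeros(400), 0.002, 3.0)
        assert abs(sz.mean()) < 1e-12

    def test_short_window_rejected(self):
        with pytest.raises(ValidationError):
            integrate_motion(np.zeros(2), np.zeros(2), 0.002, 3.0)


class TestWorkAndPower:
    def test_potential_work_hand_value(self):
        dz = np.array([0.0, -0.08, 0.0])
        wp, wk, wt = stride_work(dz, np.full(3, 3.0), 70.0)
        assert wp == pytest.approx(70 * G * 0.08, rel=1e-12)
        assert wp == pytest.approx(54.92, abs=0.01)
        assert wk == 0.0

    def test_kinetic_work_hand_value(self):
        sx = np.array([3.8, 4.2, 3.9])
        _, wk, _ = stride_work(np.zeros(3), sx, 70.0)
        assert wk == pytest.approx(0.5 * 70 * (4.2**2 - 3.8**2), rel=1e-12)
        assert wk == pytest.approx(112.0, abs=1e-9)

    def test_total_is_sum(self):
        rng = np.random.default_rng(1)
        dz, sx = rng.normal(size=100) * 0.05, 4 + rng.normal(size=100) * 0.2
        wp, wk, wt = stride_work(dz, sx, 70.0)
        assert wt == wp + wk

    def test_external_power(self):
        assert external_power(240.0, 1.4) == pytest.approx(336.0)
        assert external_power(0.0, 1.4) == 0.0
        with pytest.raises(ValidationError):
            external_power(240.0, 0.0)

    def test_mechanical_cost(self):
        assert mechanical_cost(336.0, 3.5, 70.0) == pytest.approx(1.3714, abs=1e-4)
        assert mechanical_cost(0.0, 3.5, 70.0) == 0.0
        assert mechanical_cost(336.0, 3.5, 140.0) == pytest.approx(
            mechanical_cost(336.0, 3.5, 70.0) / 2
        )
        with pytest.raises(ValidationError):
            mechanical_cost(336.0, 0.0, 70.0)


class TestOptionalLowpass:
    def test_filter_preserves_band_limited_signal(self):
        trace = half_sine_trace([0.25], [])
        from stridepower.grf_pipeline import butterworth_lowpass

        smoothed = butterworth_lowpass(trace, cutoff_hz=50.0)
        # a 0.25 s half-sine lives near 2 Hz: a 50 Hz cutoff leaves only
        # slight ringing at the slope discontinuities of the contact edges
        assert np.max(np.abs(smoothed.fz - trace.fz)) < 2e-2 * trace.fz.max()
        events = detect_contacts(smoothed)
        assert len(events) == 1 and events[0].gct == pytest.approx(0.25, abs=0.004)

    def test_invalid_cutoff_rejected(self):
        from stridepower.grf_pipeline import butterworth_lowpass

        trace = half_sine_trace([0.25], [])
        with pytest.raises(ValidationError):
            butterworth_lowpass(trace, cutoff_hz=0.0)
        with pytest.raises(ValidationError):
            butterworth_lowpass(trace, cutoff_hz=300.0)
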