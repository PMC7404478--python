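"""Synthetic incremental-track-test generator with exact ground truth.

The generator emulates a maximal-aerobic-speed (MAS) protocol on a 200 m
indoor track: speed starts at the subject's initial speed and rises by
0.5 km/h every minute, a force-platform section spans the first metres of
every lap, a heel marker is tracked optically, breath-by-breath oxygen
uptake follows first-order kinetics, and a foot-mounted power meter reports
1 Hz power / contact time / leg-spring stiffness with a configurable bias.

The runner is reduced to a spring-mass point: each step is one contact
cycle whose vertical ground reaction force is a half-sine over the contact
interval and zero in flight.  The peak force follows from whole-cycle
impulse balance,

    Fz_peak = m g (pi/2) (T / Tc),

with ``T`` the cycle period and ``Tc`` the contact time.  A full stride
(ipsilateral strike to the next ipsilateral strike) contains two such
cycles on alternating feet.  The horizontal force is a braking/propulsion
full sine with zero net impulse.  Because the waveform is analytic, every
derived quantity the reference pipeline estimates -- contact time, peak
force, vertical excursion, leg stiffness, stride works and external power
-- has a closed form recorded as ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .grf_pipeline import G, ForceTrace, ValidationError
from .stiffness_kinematics import LEG_LENGTH_RATIO, MarkerTrace


@dataclass(frozen=True)
class SubjectProfile:
    """Anthropometrics and aerobic profile of one simulated runner."""

    mass: float                    # body mass (kg)
    height: float                  # standing height (m)
    vo2_rest: float = 5.0          # resting VO2 (ml/kg/min)
    vo2max: float = 53.0           # maximal VO2 (ml/kg/min)
    initial_speed_kmh: float = 10.0

    def __post_init__(self) -> None:
        if self.mass <= 0 or self.height <= 0:
            raise ValidationError("mass and height must be positive")
        if not self.vo2_rest < self.vo2max:
            raise ValidationError("vo2_rest must be below vo2max")

    @property
    def leg_length(self) -> float:
        """Resting leg length, standardised at 0.53 of height (m)."""
        return LEG_LENGTH_RATIO * self.height


@dataclass(frozen=True)
class ProtocolConfig:
    """Incremental test and instrumentation settings."""

    lap_length: float = 200.0        # m
    platform_span: float = 9.0       # m of instrumented track per lap
    speed_increment_kmh: float = 0.5
    stage_duration_s: float = 60.0
    grf_rate: float = 500.0          # Hz
    marker_rate: float = 400.0       # Hz
    pod_rate: float = 1.0            # Hz
    max_speed_kmh: float = 19.0      # stop rule: last stage at/below this
    max_stages: int | None = None

    def __post_init__(self) -> None:
        if min(self.grf_rate, self.marker_rate, self.pod_rate) <= 0:
            raise ValidationError("all sampling rates must be positive")
        if not 0 <= self.platform_span < self.lap_length:
            raise ValidationError("platform span must lie within a lap")


@dataclass(frozen=True)
class DeviceBiasModel:
    """Additive bias + noise model of the footpod channels.

    Power bias is ``po_offset_w + po_slope_w_per_mps * speed`` so a
    speed-proportional underestimation can be injected on top of a constant
    offset.  Noise is independent Gaussian per channel.
    """

    po_offset_w: float = 0.0
    po_slope_w_per_mps: float = 0.0
    gct_offset_s: float = 0.0
    lss_offset_kn_m: float = 0.0
    noise_sd_po: float = 0.0
    noise_sd_gct: float = 0.0
    noise_sd_lss: float = 0.0

    def __post_init__(self) -> None:
        if min(self.noise_sd_po, self.noise_sd_gct, self.noise_sd_lss) < 0:
            raise ValidationError("noise standard deviations must be non-negative")

    @classmethod
    def underreading(cls) -> "DeviceBiasModel":
        """Bias regime of a footpod that underreads power: a large constant
        underestimation that grows with speed, plus modest channel noise."""
        return cls(
            po_offset_w=-300.0,
            po_slope_w_per_mps=-20.0,
            noise_sd_po=10.0,
            noise_sd_gct=0.004,
            noise_sd_lss=0.3,
        )


@dataclass(frozen=True)
class GaitModel:
    """Spring-mass gait parameters of the simulated runner.

    The stride duty factor (contact time over stride period) decreases
    linearly with speed, which produces the expected negative contact-time
    versus speed trend.  The horizontal speed fluctuation per step is a
    fixed fraction of running speed; its default puts the mechanical cost
    of running near 2.3 J/kg/m at 4 m/s, the magnitude expected from
    external-work summation on a track.
    """

    kleg_kn_m: float = 10.0
    duty_speeds: tuple[float, float] = (2.2, 5.5)    # m/s anchors
    duty_values: tuple[float, float] = (0.38, 0.28)  # stride duty factor
    sx_fluctuation_frac: float = 0.17                # delta-v as fraction of v
    marker_swing_height: float = 0.12                # heel lift in swing (m)
    marker_baseline: float = 0.02                    # heel height in stance (m)

    def duty_factor(self, speed: float) -> float:
        return float(
            np.interp(speed, self.duty_speeds, self.duty_values)
        )


@dataclass(frozen=True)
class StrideTruth:
    """Closed-form mechanics of one contact cycle (one step)."""

    speed: float       # m/s
    tc: float          # contact time (s)
    t_cycle: float     # cycle (step) period (s)
    t_stride: float    # stride period = 2 * t_cycle (s)
    fz_peak: float     # N
    dy: float          # vertical COM excursion during contact (m)
    apex: float        # COM rise above toe-off height at mid-flight (m)
    kleg: float        # kN/m
    wp: float          # J
    wk: float          # J
    wt: float          # J
    w_ext: float       # W


@dataclass
class SyntheticSession:
    """Everything one simulated MAS session produces, truth included."""

    subject: SubjectProfile
    protocol: ProtocolConfig
    bias: DeviceBiasModel
    gait: GaitModel
    seed: int
    stage_speeds_kmh: np.ndarray
    force_traces: dict[int, ForceTrace]   # lap index -> platform passage
    marker: MarkerTrace
    breaths: pd.DataFrame                 # t, vo2
    pod: pd.DataFrame                     # t, power, gct_ms, lss, distance
    truth: pd.DataFrame                   # one row per step
    truth_1hz: pd.DataFrame               # bias-free device-rate truth


# ---------------------------------------------------------------------------
# closed-form spring-mass mechanics


def peak_force(mass: float, t_cycle: float, tc: float) -> float:
    """Impulse-balance half-sine peak: ``m g (pi/2) (T/Tc)`` (N)."""
    if not 0 < tc < t_cycle:
        raise ValidationError("need 0 < Tc < cycle period")
    return mass * G * (np.pi / 2.0) * (t_cycle / tc)


def _cycle_truth(
    speed: float, subject: SubjectProfile, gait: GaitModel, tc: float, duty_stride: float
) -> StrideTruth:
    """Analytic per-cycle mechanics for a given contact time."""
    t_cycle = tc / (2.0 * duty_stride)
    tf = t_cycle - tc
    fzp = peak_force(subject.mass, t_cycle, tc)
    fm = fzp / subject.mass
    v0 = -G * tf / 2.0  # touchdown vertical velocity of the periodic orbit
    # displacement at mid-contact (minimum by symmetry)
    dz_mid = (
        v0 * tc / 2.0
        + fm * (tc / np.pi) * (tc / 2.0 - tc / np.pi)
        - G * tc * tc / 8.0
    )
    dy = abs(dz_mid)
    apex = G * tf * tf / 8.0
    dv = gait.sx_fluctuation_frac * speed
    wp = subject.mass * G * (dy + apex)
    wk = 0.5 * subject.mass * (speed**2 - (speed - dv) ** 2)
    wt = wp + wk
    # spring-mass stiffness implied by the emitted kinematics; the forward
    # velocity is the stride-mean speed (what the reference estimator uses),
    # which sits below the touchdown speed by half the contact fluctuation
    v_mean = speed - 0.5 * dv * (tc / t_cycle)
    half_sweep = v_mean * tc / (2.0 * subject.leg_length)
    theta = np.arcsin(half_sweep)
    dl = dy + subject.leg_length * (1.0 - np.cos(theta))
    return StrideTruth(
        speed=speed,
        tc=tc,
        t_cycle=t_cycle,
        t_stride=2.0 * t_cycle,
        fz_peak=fzp,
        dy=dy,
        apex=apex,
        kleg=fzp / dl / 1000.0,
        wp=wp,
        wk=wk,
        wt=wt,
        w_ext=wt / t_cycle,
    )


def solve_contact_time(
    speed: float, subject: SubjectProfile, kleg_true: float, duty_factor: float,
    gait: GaitModel | None = None,
) -> float:
    """Contact time (s) at which the emitted kinematics imply ``kleg_true``.

    With the duty factor fixed, the peak force is independent of the contact
    time while the leg compression grows with it, so the implied stiffness
    is strictly decreasing in ``Tc`` and the root is unique.
    """
    gait = gait or GaitModel()
    if speed <= 0:
        raise ValidationError("speed must be positive")
    if not 0 < duty_factor < 0.5:
        raise ValidationError(
            "stride duty factor must lie in (0, 0.5): each stride holds two "
            "alternating-foot contacts"
        )
    tc_hi = min(0.6, 0.98 * 2.0 * subject.leg_length / speed)

    def gap(tc: float) -> float:
        return _cycle_truth(speed, subject, gait, tc, duty_factor).kleg - kleg_true

    lo, hi = 0.02, tc_hi
    if gap(lo) < 0 or gap(hi) > 0:
        raise ValidationError(
            f"kleg={kleg_true} kN/m unreachable at speed {speed} m/s "
            f"with duty factor {duty_factor}"
        )
    return float(brentq(gap, lo, hi, xtol=1e-10))


def spring_mass_stride(
    speed: float,
    subject: SubjectProfile,
    kleg_true: float,
    duty_factor: float,
    gait: GaitModel | None = None,
    grf_rate: float = 500.0,
    t_start: float = 0.0,
) -> tuple[ForceTrace, StrideTruth]:
    """One full stride (two alternating-foot contact cycles) of synthetic GRF.

    Returns the 500 Hz force trace spanning exactly one stride period and
    the closed-form per-cycle ground truth.  The vertical force is a
    half-sine per contact, zero in flight; the horizontal force a full sine
    with zero net impulse.
    """
    if speed <= 0:
        raise ValidationError("speed must be positive")
    if not 0 < duty_factor < 1:
        raise ValidationError("duty factor must lie in (0, 1)")
    gait = gait or GaitModel()
    tc = solve_contact_time(speed, subject, kleg_true, duty_factor, gait)
    truth = _cycle_truth(speed, subject, gait, tc, duty_factor)
    dt = 1.0 / grf_rate
    n = int(round(truth.t_stride / dt))
    t = t_start + np.arange(n) * dt
    rel = (t - t_start) % truth.t_cycle
    in_contact = rel < tc
    fz = np.where(in_contact, truth.fz_peak * np.sin(np.pi * rel / tc), 0.0)
    dv = gait.sx_fluctuation_frac * speed
    fx_amp = dv * np.pi * subject.mass / tc
    fx = np.where(in_contact, -fx_amp * np.sin(2.0 * np.pi * rel / tc), 0.0)
    return ForceTrace(t=t, fz=fz, fx=fx, mass=subject.mass), truth


# ---------------------------------------------------------------------------
# oxygen uptake


def simulate_vo2(
    power_t: np.ndarray,
    power_w: np.ndarray,
    subject: SubjectProfile,
    tau: float = 25.0,
    noise_sd: float = 2.0,
    slope: float = 0.08,
    breath_interval_bounds: tuple[float, float] = (4.0, 1.5),
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Breath-by-breath VO2 (ml/kg/min) from a mechanical power profile.

    The noiseless steady state is affine in power, ``vo2_rest + slope * P``,
    saturating at ``vo2max``.  Transitions follow first-order kinetics with
    time constant ``tau`` (exact update for piecewise-constant input).
    Breaths are emitted by a gamma renewal process whose mean interval
    shrinks from ~4 s at rest to ~1.5 s at maximal intensity, and carry
    additive Gaussian noise.
    """
    if tau <= 0:
        raise ValidationError("tau must be positive")
    power_t = np.asarray(power_t, dtype=float)
    power_w = np.asarray(power_w, dtype=float)
    if power_t.size == 0:
        raise ValidationError("empty power profile")
    rng = rng or np.random.default_rng(0)

    vo2_ss = np.minimum(subject.vo2_rest + slope * power_w, subject.vo2max)
    vo2 = np.empty_like(vo2_ss)
    vo2[0] = subject.vo2_rest
    dts = np.diff(power_t)
    decay = np.exp(-dts / tau)
    for i in range(1, vo2.size):
        vo2[i] = vo2_ss[i] + (vo2[i - 1] - vo2_ss[i]) * decay[i - 1]

    lo, hi = breath_interval_bounds
    t_end = float(power_t[-1])
    times = []
    t = 0.0
    shape = 10.0  # gamma renewal: fairly regular breathing
    while True:
        frac = np.interp(t, power_t, (vo2_ss - subject.vo2_rest)) / max(
            subject.vo2max - subject.vo2_rest, 1e-9
        )
        mean_iv = lo + (hi - lo) * min(max(frac, 0.0), 1.0)
        t += rng.gamma(shape, mean_iv / shape)
        if t > t_end:
            break
        times.append(t)
    tb = np.asarray(times)
    vb = np.interp(tb, power_t, vo2) + rng.normal(0.0, noise_sd, size=tb.size)
    return pd.DataFrame({"t": tb, "vo2": np.maximum(vb, 0.0)})


# ---------------------------------------------------------------------------
# device bias


def apply_device_bias(
    truth: pd.DataFrame,
    bias: DeviceBiasModel,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Footpod stream from device-rate truth plus the bias model.

    ``truth`` needs columns ``t, speed, power, gct_s, lss, distance``;
    power gains ``po_offset + po_slope * speed`` plus Gaussian noise, and
    contact time / stiffness their own offsets and noise.  Distance is
    passed through unchanged (the device is assumed distance-reliable).
    """
    if truth.empty:
        raise ValidationError("empty truth stream")
    rng = rng or np.random.default_rng(0)
    n = len(truth)
    power = (
        truth["power"].to_numpy()
        + bias.po_offset_w
        + bias.po_slope_w_per_mps * truth["speed"].to_numpy()
        + rng.normal(0.0, bias.noise_sd_po, n)
    )
    gct = (
        truth["gct_s"].to_numpy()
        + bias.gct_offset_s
        + rng.normal(0.0, bias.noise_sd_gct, n)
    )
    lss = (
        truth["lss"].to_numpy()
        + bias.lss_offset_kn_m
        + rng.normal(0.0, bias.noise_sd_lss, n)
    )
    return pd.DataFrame(
        {
            "t": truth["t"].to_numpy(),
            "power": power,
            "gct_ms": gct * 1000.0,
            "lss": lss,
            "distance": truth["distance"].to_numpy(),
        }
    )


# ---------------------------------------------------------------------------
# full session


def stage_speeds(subject: SubjectProfile, protocol: ProtocolConfig) -> np.ndarray:
    """Stage speeds (km/h): initial + k * increment up to the stop rule."""
    speeds = []
    v = subject.initial_speed_kmh
    while v <= protocol.max_speed_kmh + 1e-9:
        speeds.append(v)
        if protocol.max_stages is not None and len(speeds) >= protocol.max_stages:
            break
        v += protocol.speed_increment_kmh
    if not speeds:
        raise ValidationError("protocol yields zero stages")
    return np.asarray(speeds)


def simulate_session(
    subject: SubjectProfile,
    protocol: ProtocolConfig | None = None,
    bias: DeviceBiasModel | None = None,
    gait: GaitModel | None = None,
    seed: int = 0,
    vo2_kwargs: dict | None = None,
) -> SyntheticSession:
    """Generate a complete synthetic MAS session with ground truth.

    All randomness derives from ``seed`` through independent per-channel
    streams (pod noise, VO2 noise/breath timing), so adding noise to one
    channel never perturbs another and identical seeds give identical
    sessions.
    """
    protocol = protocol or ProtocolConfig()
    bias = bias or DeviceBiasModel()
    gait = gait or GaitModel()
    ss = np.random.SeedSequence(seed)
    rng_pod, rng_vo2 = (np.random.default_rng(s) for s in ss.spawn(2))

    speeds_kmh = stage_speeds(subject, protocol)
    speeds = speeds_kmh / 3.6
    n_stages = speeds.size
    stage_dur = protocol.stage_duration_s
    total_time = n_stages * stage_dur

    # per-stage cached gait solution
    stage_cache: list[StrideTruth] = []
    for v in speeds:
        df = gait.duty_factor(v)
        tc = solve_contact_time(v, subject, gait.kleg_kn_m, df, gait)
        stage_cache.append(_cycle_truth(v, subject, gait, tc, df))

    # step-by-step timeline
    rows = []
    t, pos, foot = 0.0, 0.0, 0
    while t < total_time - 1e-9:
        stage = min(int(t // stage_dur), n_stages - 1)
        ct = stage_cache[stage]
        rows.append(
            (t, pos, foot, stage, ct.speed, ct.tc, ct.t_cycle, ct.t_stride,
             ct.fz_peak, ct.dy, ct.kleg, ct.wp, ct.wk, ct.wt, ct.w_ext)
        )
        t += ct.t_cycle
        pos += ct.speed * ct.t_cycle
        foot ^= 1
    truth = pd.DataFrame(
        rows,
        columns=[
            "t", "pos", "foot", "stage", "speed", "tc", "t_cycle", "t_stride",
            "fz_peak", "dy", "kleg", "wp", "wk", "wt", "w_ext",
        ],
    )
    if truth.empty:
        raise ValidationError("session produced no steps")
    truth["lap"] = -1

    # platform passages: steps whose strike lies in [k*L, k*L + span)
    grf_dt = 1.0 / protocol.grf_rate
    force_traces: dict[int, ForceTrace] = {}
    n_laps = int(truth["pos"].iloc[-1] // protocol.lap_length) + 1
    strike_pos = truth["pos"].to_numpy()
    for lap in range(n_laps):
        start = lap * protocol.lap_length
        in_win = np.flatnonzero(
            (strike_pos >= start) & (strike_pos < start + protocol.platform_span)
        )
        if in_win.size == 0:
            continue
        truth.loc[truth.index[in_win], "lap"] = lap
        first, last = in_win[0], min(in_win[-1] + 2, len(truth) - 1)
        steps = truth.iloc[first : last + 1]
        t0 = steps["t"].iloc[0] - 0.025
        t1 = steps["t"].iloc[-1] + steps["tc"].iloc[-1] + 0.025
        # align the grid to the global 500 Hz lattice for cross-lap coherence
        i0 = int(np.ceil(t0 / grf_dt))
        n = int(np.floor(t1 / grf_dt)) - i0 + 1
        tg = (i0 + np.arange(n)) * grf_dt
        fz = np.zeros(n)
        fx = np.zeros(n)
        for _, st in steps.iterrows():
            rel = tg - st["t"]
            m = (rel >= 0) & (rel < st["tc"])
            fz[m] += st["fz_peak"] * np.sin(np.pi * rel[m] / st["tc"])
            dv = gait.sx_fluctuation_frac * st["speed"]
            amp = dv * np.pi * subject.mass / st["tc"]
            fx[m] += -amp * np.sin(2.0 * np.pi * rel[m] / st["tc"])
        force_traces[lap] = ForceTrace(t=tg, fz=fz, fx=fx, mass=subject.mass)

    # heel marker (ipsilateral foot = 0) over the whole session
    mk_dt = 1.0 / protocol.marker_rate
    tg = np.arange(0.0, total_time, mk_dt)
    z = np.full(tg.size, gait.marker_baseline)
    left = truth[truth["foot"] == 0].reset_index(drop=True)
    for i in range(len(left) - 1):
        toe_off = left["t"].iloc[i] + left["tc"].iloc[i]
        next_strike = left["t"].iloc[i + 1]
        j0 = int(np.ceil(toe_off / mk_dt))
        j1 = min(int(np.floor(next_strike / mk_dt)), tg.size - 1)
        if j1 <= j0:
            continue
        phase = (tg[j0 : j1 + 1] - toe_off) / (next_strike - toe_off)
        z[j0 : j1 + 1] += gait.marker_swing_height * np.sin(np.pi * phase) ** 2
    marker = MarkerTrace(t=tg, z=z)

    # device-rate truth and biased footpod stream
    t_pod = np.arange(0.0, total_time, 1.0 / protocol.pod_rate)
    step_idx = np.clip(
        np.searchsorted(truth["t"].to_numpy(), t_pod, side="right") - 1, 0, None
    )
    stage_starts = np.arange(n_stages) * stage_dur
    stage_cumdist = np.concatenate([[0.0], np.cumsum(speeds * stage_dur)])
    pod_stage = np.minimum((t_pod // stage_dur).astype(int), n_stages - 1)
    distance = stage_cumdist[pod_stage] + speeds[pod_stage] * (
        t_pod - stage_starts[pod_stage]
    )
    truth_1hz = pd.DataFrame(
        {
            "t": t_pod,
            "speed": truth["speed"].to_numpy()[step_idx],
            "power": truth["w_ext"].to_numpy()[step_idx],
            "gct_s": truth["tc"].to_numpy()[step_idx],
            "lss": truth["kleg"].to_numpy()[step_idx],
            "distance": distance,
        }
    )
    pod = apply_device_bias(truth_1hz, bias, rng_pod)

    breaths = simulate_vo2(
        truth_1hz["t"].to_numpy(),
        truth_1hz["power"].to_numpy(),
        subject,
        rng=rng_vo2,
        **(vo2_kwargs or {}),
    )

    return SyntheticSession(
        subject=subject,
        protocol=protocol,
        bias=bias,
        gait=gait,
        seed=seed,
        stage_speeds_kmh=speeds_kmh,
        force_traces=force_traces,
        marker=marker,
        breaths=breaths,
        pod=pod,
        truth=truth,
        truth_1hz=truth_1hz,
    )
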