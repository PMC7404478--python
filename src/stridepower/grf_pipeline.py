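"""Force-platform kinetics: contact detection, stride works, external power.

The reference chain implemented here follows the external energy summation
approach classically used with track-embedded force platforms: the vertical
and anterior-posterior ground reaction forces are converted to centre-of-mass
accelerations, integrated twice over a stride window, and the potential and
kinetic work increments are summed (no energy-transfer term) to give the
total stride work ``Wt``.  External mechanical power is ``W_ext = Wt * omega``
with ``omega`` the stride-derived frequency, and the mechanical cost of
running normalises it by speed and body mass.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import cumulative_trapezoid

G = 9.80665
"""Standard gravity (m/s^2), used everywhere a weight enters the mechanics."""

#: Default vertical-force threshold (N) for contact detection on a 500 Hz
#: platform, with a 10 ms debounce discarding spuriously short contacts.
DEFAULT_THRESHOLD = 20.0
DEFAULT_DEBOUNCE_S = 0.010


class ValidationError(ValueError):
    """Raised when an input violates a physical or structural precondition."""


@dataclass(frozen=True)
class ForceTrace:
    """Uniformly sampled vertical/horizontal GRF from one platform passage.

    Attributes
    ----------
    t : ndarray
        Time stamps (s), strictly increasing with constant step.
    fz, fx : ndarray
        Vertical and anterior-posterior force components (N).
    mass : float
        Subject body mass (kg).
    """

    t: np.ndarray
    fz: np.ndarray
    fx: np.ndarray
    mass: float

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        fz = np.asarray(self.fz, dtype=float)
        fx = np.asarray(self.fx, dtype=float)
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "fz", fz)
        object.__setattr__(self, "fx", fx)
        if t.ndim != 1 or t.size != fz.size or t.size != fx.size:
            raise ValidationError("t, fz, fx must be 1-D arrays of equal length")
        if not (np.isfinite(fz).all() and np.isfinite(fx).all() and np.isfinite(t).all()):
            raise ValidationError("force trace contains non-finite values")
        if self.mass <= 0:
            raise ValidationError(f"subject mass must be positive, got {self.mass}")
        if t.size >= 2:
            steps = np.diff(t)
            if steps.min() <= 0:
                raise ValidationError("time axis must be strictly increasing")
            if not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-9):
                raise ValidationError("non-uniform sampling detected in force trace")

    @property
    def dt(self) -> float:
        if self.t.size < 2:
            raise ValidationError("trace too short to define a sampling step")
        return float(self.t[1] - self.t[0])

    @property
    def rate(self) -> float:
        return 1.0 / self.dt


@dataclass(frozen=True)
class ContactEvent:
    """One foot-ground contact delimited on the vertical GRF."""

    strike_time: float
    toe_off_time: float
    peak_force: float
    strike_index: int
    toe_off_index: int  # first sample past the contact (exclusive)

    @property
    def gct(self) -> float:
        """Ground contact time (s)."""
        return self.toe_off_time - self.strike_time


@dataclass(frozen=True)
class StrideMetrics:
    """Per-stride mechanical quantities derived from one stride window."""

    speed: float          # mean horizontal speed Sx (m/s)
    wp: float             # potential work (J)
    wk: float             # kinetic work (J)
    wt: float             # total work (J), wp + wk
    omega: float          # stride-derived frequency (Hz)
    w_ext: float          # external mechanical power (W)
    cm: float             # mechanical cost of running (J/kg/m)
    dz_range: float       # vertical COM excursion over the window (m)
    sx_range: float       # horizontal speed fluctuation over the window (m/s)
    gct: float            # contact time of the leading contact (s)
    peak_force: float     # peak vertical force of the leading contact (N)


def detect_contacts(
    trace: ForceTrace,
    threshold: float = DEFAULT_THRESHOLD,
    debounce_s: float = DEFAULT_DEBOUNCE_S,
) -> list[ContactEvent]:
    """Delimit foot contacts where ``fz`` exceeds ``threshold``.

    A contact opens at the first sample with ``fz >= threshold`` and closes
    at the first subsequent sample with ``fz < threshold``; those sample
    indices delimit the contact window.  The reported strike and toe-off
    times refine the sample instants by linear interpolation of the
    threshold crossing between adjacent samples, so the contact duration is
    not quantised to the sampling step.  Contacts shorter than
    ``debounce_s`` are discarded as noise.  An empty or all-quiet trace
    yields an empty list.
    """
    if threshold <= 0:
        raise ValidationError("threshold must be positive")
    if trace.t.size == 0:
        return []
    above = trace.fz >= threshold
    if not above.any():
        return []
    edges = np.diff(above.astype(np.int8))
    starts = np.flatnonzero(edges == 1) + 1
    ends = np.flatnonzero(edges == -1) + 1
    if above[0]:
        starts = np.r_[0, starts]
    if above[-1]:
        ends = np.r_[ends, above.size]
    dt = trace.dt
    events: list[ContactEvent] = []
    for s, e in zip(starts, ends):
        if s > 0 and trace.fz[s] > trace.fz[s - 1]:
            frac = (threshold - trace.fz[s - 1]) / (trace.fz[s] - trace.fz[s - 1])
            t_on = trace.t[s - 1] + frac * dt
        else:
            t_on = trace.t[s]
        if e < trace.t.size and trace.fz[e - 1] > trace.fz[e]:
            frac = (trace.fz[e - 1] - threshold) / (trace.fz[e - 1] - trace.fz[e])
            t_off = trace.t[e - 1] + frac * dt
        else:
            t_off = trace.t[e] if e < trace.t.size else trace.t[-1] + dt
        if t_off - t_on < debounce_s:
            continue
        events.append(
            ContactEvent(
                strike_time=float(t_on),
                toe_off_time=float(t_off),
                peak_force=float(trace.fz[s:e].max()),
                strike_index=int(s),
                toe_off_index=int(e),
            )
        )
    return events


def butterworth_lowpass(
    trace: ForceTrace, cutoff_hz: float, order: int = 4
) -> ForceTrace:
    """Optional zero-phase Butterworth low-pass of both force channels.

    Off by default throughout the pipeline: synthetic traces are
    band-limited by construction.  Available for real platform data with
    high-frequency noise.
    """
    from scipy.signal import butter, filtfilt

    if cutoff_hz <= 0 or cutoff_hz >= trace.rate / 2:
        raise ValidationError("cutoff must lie in (0, Nyquist)")
    b, a = butter(order, cutoff_hz, fs=trace.rate)
    return ForceTrace(
        t=trace.t,
        fz=filtfilt(b, a, trace.fz),
        fx=filtfilt(b, a, trace.fx),
        mass=trace.mass,
    )


def decompose_acceleration(trace: ForceTrace) -> tuple[np.ndarray, np.ndarray]:
    """COM acceleration components from the measured forces.

    ``Az = (Fz - m g)/m`` and ``Ax = Fx/m``; gravity is subtracted only on
    the vertical axis.
    """
    az = (trace.fz - trace.mass * G) / trace.mass
    ax = trace.fx / trace.mass
    return az, ax


def integrate_motion(
    az: np.ndarray,
    ax: np.ndarray,
    dt: float,
    initial_sx: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Recursive (cumulative trapezoidal) integration over one stride window.

    The horizontal velocity is anchored at the prescribed stage speed
    ``initial_sx``; the vertical velocity constant is chosen so the
    stride-mean vertical velocity is zero, the steady-state condition for
    paced track running.  Displacements start at zero.
    """
    az = np.asarray(az, dtype=float)
    ax = np.asarray(ax, dtype=float)
    if az.size < 3:
        raise ValidationError("stride window shorter than 3 samples")
    if az.size != ax.size:
        raise ValidationError("az and ax must have equal length")
    sz_raw = cumulative_trapezoid(az, dx=dt, initial=0.0)
    sz = sz_raw - sz_raw.mean()
    sx = cumulative_trapezoid(ax, dx=dt, initial=0.0) + initial_sx
    dz = cumulative_trapezoid(sz, dx=dt, initial=0.0)
    dx = cumulative_trapezoid(sx, dx=dt, initial=0.0)
    return sz, sx, dz, dx


def stride_work(dz: np.ndarray, sx: np.ndarray, mass: float) -> tuple[float, float, float]:
    """Potential, kinetic and total work over one stride window.

    ``Wp = m g (max Dz - min Dz)``; ``Wk = m/2 (max Sx^2 - min Sx^2)``;
    ``Wt = Wp + Wk`` (summation without an energy-transfer term).
    """
    if mass <= 0:
        raise ValidationError("mass must be positive")
    dz = np.asarray(dz, dtype=float)
    sx = np.asarray(sx, dtype=float)
    wp = mass * G * (dz.max() - dz.min())
    wk = 0.5 * mass * (np.max(sx) ** 2 - np.min(sx) ** 2)
    return float(wp), float(wk), float(wp + wk)


def external_power(wt: float, omega: float) -> float:
    """External mechanical power ``W_ext = Wt * omega`` (W)."""
    if omega <= 0:
        raise ValidationError("stride frequency must be positive")
    return wt * omega


def mechanical_cost(w_ext: float, speed: float, mass: float) -> float:
    """Mechanical cost of running ``Cm = W_ext / (Sx * m)`` (J/kg/m)."""
    if speed <= 0 or mass <= 0:
        raise ValidationError("speed and mass must be positive")
    return w_ext / (speed * mass)


def analyze_trace(
    trace: ForceTrace,
    stage_speed: float,
    threshold: float = DEFAULT_THRESHOLD,
    debounce_s: float = DEFAULT_DEBOUNCE_S,
) -> list[StrideMetrics]:
    """Full per-stride analysis of one platform passage.

    Stride windows run from each contact's strike to the strike two contacts
    later (ipsilateral strike to ipsilateral strike, successive contacts
    alternating feet).  For each window the accelerations are integrated,
    works and external power computed, and the stride frequency taken as
    ``omega = 1/Ts`` with ``Ts = (C2 - C1)/2`` for the ipsilateral strike
    pair -- numerically a step rate, kept as the convention of the reference
    method.
    """
    contacts = detect_contacts(trace, threshold=threshold, debounce_s=debounce_s)
    out: list[StrideMetrics] = []
    if len(contacts) < 3:
        return out
    az, ax = decompose_acceleration(trace)
    dt = trace.dt
    for lead, closing in zip(contacts, contacts[2:]):
        i0, i1 = lead.strike_index, closing.strike_index
        if i1 - i0 < 3:
            continue
        window = slice(i0, i1)
        _, sx, dz, _ = integrate_motion(az[window], ax[window], dt, stage_speed)
        wp, wk, wt = stride_work(dz, sx, trace.mass)
        ts = (closing.strike_time - lead.strike_time) / 2.0
        omega = 1.0 / ts
        w_ext = external_power(wt, omega)
        mean_sx = float(sx.mean())
        out.append(
            StrideMetrics(
                speed=mean_sx,
                wp=wp,
                wk=wk,
                wt=wt,
                omega=omega,
                w_ext=w_ext,
                cm=mechanical_cost(w_ext, mean_sx, trace.mass),
                dz_range=float(dz.max() - dz.min()),
                sx_range=float(sx.max() - sx.min()),
                gct=lead.gct,
                peak_force=lead.peak_force,
            )
        )
    return out


def aggregate_strides(strides: list[StrideMetrics]) -> dict[str, float]:
    """Unweighted mean of each metric across the valid strides of one lap."""
    if not strides:
        return {}
    fields = (
        "speed wp wk wt omega w_ext cm dz_range sx_range gct peak_force".split()
    )
    return {f: float(np.mean([getattr(s, f) for s in strides])) for f in fields}
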