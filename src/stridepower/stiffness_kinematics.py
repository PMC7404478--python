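"""Spring-mass leg stiffness and heel-marker stride timing.

Leg stiffness follows the McMahon & Cheng planar spring-mass geometry: during
stance the leg spring of resting length ``L`` sweeps a half-angle ``theta``
while compressing by ``dL = dy + L (1 - cos theta)``, where ``dy`` is the
vertical excursion of the centre of mass.  Stiffness is the ratio of the peak
vertical force to that compression, ``kleg = Fz_peak / dL``, reported in
kN/m to match the footpod's leg-spring-stiffness channel.

The half-angle satisfies ``sin theta = v Tc / (2 L)`` (forward travel of the
hip over half the contact relative to leg length).  Some descriptions print
this relation as ``theta = sin(v Tc / 2L)``, which is dimensionally a
different quantity; ``literal_theta=True`` reproduces that reading for
comparison purposes, the default uses the arcsine geometry.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.signal import find_peaks

from .grf_pipeline import ValidationError

#: Leg resting length as a fraction of standing height.
LEG_LENGTH_RATIO = 0.53


@dataclass(frozen=True)
class MarkerTrace:
    """Vertical heel-marker trajectory from optical motion capture (400 Hz)."""

    t: np.ndarray
    z: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        z = np.asarray(self.z, dtype=float)
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "z", z)
        if t.size != z.size or t.ndim != 1:
            raise ValidationError("marker t and z must be 1-D of equal length")
        if not (np.isfinite(t).all() and np.isfinite(z).all()):
            raise ValidationError("marker trace contains non-finite values")
        if t.size >= 2:
            steps = np.diff(t)
            if steps.min() <= 0 or not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-9):
                raise ValidationError("marker trace must be uniformly sampled")

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])


@dataclass(frozen=True)
class StiffnessResult:
    """Spring-mass quantities for one contact."""

    kleg: float      # leg stiffness (kN/m)
    peak_force: float  # peak vertical force (N)
    dy: float        # vertical COM excursion during contact (m)
    dl: float        # leg compression (m)
    theta: float     # half sweep angle (rad)
    v: float         # forward speed (m/s)
    tc: float        # contact time (s)
    leg_length: float  # resting leg length (m)


def vertical_com_displacement(
    az_contact: np.ndarray, dt: float, entry_sz: float
) -> float:
    """Downward COM excursion (m) over a contact, by double integration.

    ``az_contact`` is the vertical COM acceleration over the contact samples;
    ``entry_sz`` the vertical velocity at touchdown taken from the
    stride-level integration.  The magnitude of the minimum of the resulting
    displacement curve is returned.
    """
    az_contact = np.asarray(az_contact, dtype=float)
    if az_contact.size < 3:
        raise ValidationError("contact window shorter than 3 samples")
    sz = cumulative_trapezoid(az_contact, dx=dt, initial=0.0) + entry_sz
    dz = cumulative_trapezoid(sz, dx=dt, initial=0.0)
    return float(abs(dz.min()))


def leg_stiffness(
    peak_force: float,
    dy: float,
    v: float,
    tc: float,
    leg_length: float,
    literal_theta: bool = False,
) -> StiffnessResult:
    """McMahon-Cheng leg stiffness from contact-level quantities.

    Parameters are the peak vertical force (N), the vertical COM excursion
    ``dy`` (m), the forward speed ``v`` (m/s), the contact time ``tc`` (s)
    and the resting leg length (m).  Returns stiffness in kN/m.
    """
    if leg_length <= 0:
        raise ValidationError("leg length must be positive")
    half_sweep = v * tc / (2.0 * leg_length)
    if not 0.0 <= half_sweep < 1.0:
        raise ValidationError(
            f"v*Tc/(2L) = {half_sweep:.3f} outside [0, 1): non-physical sweep"
        )
    theta = half_sweep if literal_theta else float(np.arcsin(half_sweep))
    dl = dy + leg_length * (1.0 - np.cos(theta))
    if dl <= 0:
        raise ValidationError("non-positive leg compression")
    return StiffnessResult(
        kleg=peak_force / dl / 1000.0,
        peak_force=peak_force,
        dy=dy,
        dl=float(dl),
        theta=theta,
        v=v,
        tc=tc,
        leg_length=leg_length,
    )


def stride_time(strike_times: np.ndarray) -> tuple[float, float]:
    """Stride time and frequency from consecutive ipsilateral heel strikes.

    ``Ts = (C2 - C1)/2`` for each consecutive strike pair (equal stride
    properties between limbs assumed), averaged when more than two strikes
    are given; ``omega = 1/Ts``.
    """
    strikes = np.asarray(strike_times, dtype=float)
    if strikes.size < 2:
        raise ValidationError("need at least two heel strikes")
    gaps = np.diff(strikes)
    if gaps.min() <= 0:
        raise ValidationError("strike times must be strictly increasing")
    ts = float(np.mean(gaps) / 2.0)
    return ts, 1.0 / ts


def detect_heel_strikes(
    marker: MarkerTrace,
    stride_period_hint: float = 0.7,
    height_margin: float = 0.005,
) -> np.ndarray:
    """Heel-strike times from local minima of the heel height.

    Minima must fall below the 10th percentile of ``z`` plus a 5 mm margin
    and be separated by at least 0.4 stride periods; an empty array is
    returned when nothing qualifies.
    """
    z = marker.z
    if z.size < 3 or np.ptp(z) < 1e-9:
        return np.array([])
    ceiling = np.percentile(z, 10) + height_margin
    min_sep = max(1, int(round(0.4 * stride_period_hint / marker.dt)))
    # the heel often sits on a flat plateau through stance: the strike is
    # the moment it first reaches the plateau, i.e. the left edge
    idx, props = find_peaks(-z, height=-ceiling, distance=min_sep, plateau_size=1)
    strikes = props.get("left_edges", idx)
    return marker.t[strikes]


def flight_time(
    marker: MarkerTrace,
    threshold: float | None = None,
    stride_period_hint: float = 0.7,
) -> np.ndarray:
    """Airborne intervals of the instrumented foot, from heel height changes.

    Each interval runs from the heel rising through ``threshold`` (toe-off)
    to its next fall below it (strike).  The threshold defaults to the 10th
    percentile of ``z`` plus 5 mm.
    """
    z = marker.z
    if threshold is None:
        threshold = float(np.percentile(z, 10) + 0.005)
    up = z > threshold
    edges = np.diff(up.astype(np.int8))
    rises = np.flatnonzero(edges == 1) + 1
    falls = np.flatnonzero(edges == -1) + 1
    times = []
    for r in rises:
        nxt = falls[falls > r]
        if nxt.size:
            times.append(marker.t[nxt[0]] - marker.t[r])
    return np.asarray(times)


def analyze_contact_stiffness(
    az: np.ndarray,
    dt: float,
    contact_slice: slice,
    entry_sz: float,
    peak_force: float,
    v: float,
    leg_length: float,
    literal_theta: bool = False,
) -> StiffnessResult:
    """Convenience wrapper: excursion + stiffness for one delimited contact."""
    az_contact = np.asarray(az, dtype=float)[contact_slice]
    dy = vertical_com_displacement(az_contact, dt, entry_sz)
    tc = az_contact.size * dt
    return leg_stiffness(peak_force, dy, v, tc, leg_length, literal_theta=literal_theta)
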