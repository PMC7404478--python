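"""End-to-end processing of one session: traces -> per-lap reference table.

Chains the force-platform pipeline, the spring-mass stiffness estimator and
the metabolic chain over all platform passages of a session, producing the
per-lap reference metrics that the device stream is compared against.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import grf_pipeline as gp
from . import metabolic as met
from . import stiffness_kinematics as sk
from .alignment import build_comparison_table, match_lap_segments
from .simulate import SyntheticSession


@dataclass
class SessionResults:
    """All per-lap tables derived from one subject's session."""

    subject_id: str
    reference_laps: pd.DataFrame    # lap, speed, power, gct_ms, lss, cm, ...
    device_laps: pd.DataFrame       # platform-window means of the pod stream
    metabolic: pd.DataFrame         # 1 Hz filtered VO2 / metabolic power
    efficiency: pd.DataFrame        # stage-mean mechanical efficiency
    comparison: pd.DataFrame        # long-format device-vs-reference table


def process_trace(
    trace: gp.ForceTrace,
    stage_speed: float,
    leg_length: float,
    threshold: float = gp.DEFAULT_THRESHOLD,
    literal_theta: bool = False,
) -> pd.DataFrame:
    """Per-stride mechanics plus spring-mass stiffness for one passage.

    Stride windows span ipsilateral strikes (contact ``i`` to contact
    ``i+2``).  The stiffness entry velocity is the window-start vertical
    velocity from the stride-level integration, whose constant is fixed by
    the zero-mean condition.
    """
    contacts = gp.detect_contacts(trace, threshold=threshold)
    rows = []
    if len(contacts) < 3:
        return pd.DataFrame(rows)
    az, ax = gp.decompose_acceleration(trace)
    dt = trace.dt
    for lead, closing in zip(contacts, contacts[2:]):
        i0, i1 = lead.strike_index, closing.strike_index
        if i1 - i0 < 3:
            continue
        sz, sx, dz, _ = gp.integrate_motion(az[i0:i1], ax[i0:i1], dt, stage_speed)
        wp, wk, wt = gp.stride_work(dz, sx, trace.mass)
        ts = (closing.strike_time - lead.strike_time) / 2.0
        omega = 1.0 / ts
        w_ext = gp.external_power(wt, omega)
        mean_sx = float(sx.mean())
        n_contact = lead.toe_off_index - lead.strike_index
        dy = sk.vertical_com_displacement(az[i0 : i0 + n_contact], dt, float(sz[0]))
        stiff = sk.leg_stiffness(
            lead.peak_force, dy, mean_sx, lead.gct, leg_length,
            literal_theta=literal_theta,
        )
        rows.append(
            {
                "strike_time": lead.strike_time,
                "speed": mean_sx,
                "gct": lead.gct,
                "peak_force": lead.peak_force,
                "ts": ts,
                "omega": omega,
                "wp": wp,
                "wk": wk,
                "wt": wt,
                "w_ext": w_ext,
                "cm": gp.mechanical_cost(w_ext, mean_sx, trace.mass),
                "dy": dy,
                "kleg": stiff.kleg,
                "theta": stiff.theta,
            }
        )
    return pd.DataFrame(rows)


def process_session(
    session: SyntheticSession,
    subject_id: str = "S00",
    habituation_s: float = met.DEFAULT_HABITUATION_S,
    efficiency_tail_s: float | None = 30.0,
    threshold: float = gp.DEFAULT_THRESHOLD,
) -> SessionResults:
    """Reference + device per-lap tables for one synthetic session."""
    protocol = session.protocol
    subject = session.subject
    stage_dur = protocol.stage_duration_s
    speeds = session.stage_speeds_kmh / 3.6

    ref_rows = []
    for lap, trace in sorted(session.force_traces.items()):
        t_mid = 0.5 * (trace.t[0] + trace.t[-1])
        stage = min(int(t_mid // stage_dur), speeds.size - 1)
        strides = process_trace(
            trace, float(speeds[stage]), subject.leg_length, threshold=threshold
        )
        if strides.empty:
            continue
        ref_rows.append(
            {
                "lap": lap,
                "stage": stage,
                "speed": float(speeds[stage]),
                "power": float(strides["w_ext"].mean()),
                "gct_ms": float(strides["gct"].mean() * 1000.0),
                "lss": float(strides["kleg"].mean()),
                "cm": float(strides["cm"].mean()),
                "omega": float(strides["omega"].mean()),
                "peak_force": float(strides["peak_force"].mean()),
                "dy": float(strides["dy"].mean()),
                "n_strides": len(strides),
            }
        )
    reference_laps = pd.DataFrame(ref_rows)

    metabolic_1hz = met.process_breaths(
        session.breaths,
        subject.mass,
        vo2_rest=subject.vo2_rest,
        habituation_s=habituation_s,
    )
    if not reference_laps.empty:
        w_by_stage = (
            reference_laps.groupby("stage")["power"].mean().to_dict()
        )
    else:
        w_by_stage = {}
    efficiency = met.stage_efficiency(
        metabolic_1hz, w_by_stage, stage_duration_s=stage_dur, tail_s=efficiency_tail_s
    )

    device_laps = match_lap_segments(
        session.pod,
        lap_length=protocol.lap_length,
        platform_span=protocol.platform_span,
    )
    comparison = build_comparison_table(device_laps, reference_laps, subject_id)
    return SessionResults(
        subject_id=subject_id,
        reference_laps=reference_laps,
        device_laps=device_laps,
        metabolic=metabolic_1hz,
        efficiency=efficiency,
        comparison=comparison,
    )
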