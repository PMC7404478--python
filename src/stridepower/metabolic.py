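"""Breath-by-breath VO2 processing, metabolic power and efficiency.

The fixed processing order is: resample to 1 Hz (linear interpolation),
smooth with a five-sample centred moving average ("5 s time bins"),
truncate the habituation window, convert to metabolic power with the
21.1 J per ml O2 energy equivalent, and finally form the net mechanical
efficiency against a resting baseline.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .grf_pipeline import ValidationError

#: Energy equivalent of 1 ml O2 (J).
K_O2 = 21.1

#: Default resting VO2 baseline (ml/kg/min) when no pre-test window exists.
DEFAULT_VO2_REST = 5.0

#: Default habituation cutoff (s): the first minute of exercise is dropped
#: because VO2 lags the instantaneous power step at exercise onset.
DEFAULT_HABITUATION_S = 60.0


def resample_to_seconds(breaths: pd.DataFrame) -> pd.DataFrame:
    """Linear interpolation of irregular breaths onto integer seconds.

    Output spans ``[ceil(t_first), floor(t_last)]``; no extrapolation.
    """
    t = np.asarray(breaths["t"], dtype=float)
    v = np.asarray(breaths["vo2"], dtype=float)
    if t.size < 2:
        raise ValidationError("need at least two breaths to interpolate")
    if np.any(np.diff(t) <= 0):
        raise ValidationError("breath times must be strictly increasing")
    lo, hi = int(np.ceil(t[0])), int(np.floor(t[-1]))
    if hi < lo:
        raise ValidationError("breath series spans less than one second")
    ts = np.arange(lo, hi + 1, dtype=float)
    return pd.DataFrame({"t": ts, "vo2": np.interp(ts, t, v)})


def moving_average(values: np.ndarray, order: int = 5) -> np.ndarray:
    """Centred FIR mean of ``order`` samples with shrinking-window edges.

    At the series edges the window shrinks to the available samples, so no
    data are discarded and a constant series passes through unchanged.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValidationError("empty series")
    if order < 1 or order % 2 == 0:
        raise ValidationError("order must be odd and >= 1")
    half = order // 2
    csum = np.cumsum(np.r_[0.0, values])
    idx = np.arange(values.size)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half, values.size - 1)
    return (csum[hi + 1] - csum[lo]) / (hi - lo + 1)


def truncate_habituation(
    series: pd.DataFrame, cutoff_s: float = DEFAULT_HABITUATION_S
) -> pd.DataFrame:
    """Drop all samples earlier than ``cutoff_s`` from session start."""
    if cutoff_s < 0:
        raise ValidationError("cutoff must be non-negative")
    return series[series["t"] >= cutoff_s].reset_index(drop=True)


def metabolic_power(vo2: np.ndarray | float, mass: float) -> np.ndarray | float:
    """Metabolic power (W): ``vo2 * m / 60 * 21.1`` with vo2 in ml/kg/min."""
    if mass <= 0:
        raise ValidationError("mass must be positive")
    vo2 = np.asarray(vo2, dtype=float)
    if np.any(vo2 < 0):
        raise ValidationError("negative VO2")
    out = vo2 * mass / 60.0 * K_O2
    return float(out) if out.ndim == 0 else out


def mechanical_efficiency(w_ext: float, delta_w_met: float) -> float:
    """Net mechanical efficiency (%): external over net metabolic power."""
    if delta_w_met <= 0:
        raise ValidationError(
            "net metabolic power must be positive (check resting baseline)"
        )
    return w_ext / delta_w_met * 100.0


def process_breaths(
    breaths: pd.DataFrame,
    mass: float,
    vo2_rest: float = DEFAULT_VO2_REST,
    filter_order: int = 5,
    habituation_s: float = DEFAULT_HABITUATION_S,
) -> pd.DataFrame:
    """Full chain: resample -> filter -> truncate -> power columns.

    Returns a 1 Hz table with ``t, vo2_filtered, w_met, dw_met`` where
    ``dw_met`` is metabolic power net of the resting baseline.
    """
    sec = resample_to_seconds(breaths)
    filtered = moving_average(sec["vo2"].to_numpy(), order=filter_order)
    out = pd.DataFrame({"t": sec["t"], "vo2_filtered": filtered})
    out = truncate_habituation(out, habituation_s)
    w_met = metabolic_power(out["vo2_filtered"].to_numpy(), mass)
    out["w_met"] = w_met
    out["dw_met"] = w_met - metabolic_power(vo2_rest, mass)
    return out


def stage_efficiency(
    metabolic_1hz: pd.DataFrame,
    w_ext_by_stage: dict[int, float],
    stage_duration_s: float = 60.0,
    tail_s: float | None = None,
) -> pd.DataFrame:
    """Stage-mean net mechanical efficiency.

    For each stage the mean of ``dw_met`` over the stage (or over its final
    ``tail_s`` seconds, to sit on the equilibrated part of the response) is
    paired with the stage's external mechanical power.
    """
    rows = []
    for stage, w_ext in sorted(w_ext_by_stage.items()):
        t0, t1 = stage * stage_duration_s, (stage + 1) * stage_duration_s
        if tail_s is not None:
            t0 = max(t0, t1 - tail_s)
        sel = metabolic_1hz[(metabolic_1hz["t"] >= t0) & (metabolic_1hz["t"] < t1)]
        if sel.empty:
            continue
        dwm = float(sel["dw_met"].mean())
        if dwm <= 0:
            continue
        rows.append(
            {
                "stage": stage,
                "w_ext": w_ext,
                "dw_met": dwm,
                "me_pct": mechanical_efficiency(w_ext, dwm),
            }
        )
    return pd.DataFrame(rows)
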