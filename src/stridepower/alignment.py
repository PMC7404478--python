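"""Matching footpod records to force-platform passages, lap by lap.

The platform section spans the first metres of each lap; device samples
whose cumulative distance falls inside that half-open window are averaged
to one value per lap per channel, mirroring the averaging of the reference
metrics over the platform contacts.  Laps without device samples are
flagged missing rather than erroring, since unbalanced designs are part of
the downstream mixed-model contract.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .grf_pipeline import ValidationError


def match_lap_segments(
    pod: pd.DataFrame,
    lap_length: float = 200.0,
    platform_span: float = 9.0,
    window_offset: float = 0.0,
) -> pd.DataFrame:
    """Per-lap means of the footpod channels over the platform window.

    Lap ``k``'s window is ``[k*lap_length + offset, k*lap_length + offset +
    platform_span)`` in cumulative-distance space.  Returns one row per lap
    with ``n_samples == 0`` marking missing laps.
    """
    if lap_length <= 0:
        raise ValidationError("lap length must be positive")
    d = pod["distance"].to_numpy()
    if np.any(np.diff(d) < 0):
        raise ValidationError("pod cumulative distance must be non-decreasing")
    n_laps = int(d[-1] // lap_length) + 1
    rows = []
    for k in range(n_laps):
        start = k * lap_length + window_offset
        sel = pod[(d >= start) & (d < start + platform_span)]
        row = {"lap": k, "n_samples": len(sel)}
        for col in ("power", "gct_ms", "lss"):
            row[col] = float(sel[col].mean()) if len(sel) else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def build_comparison_table(
    device_laps: pd.DataFrame,
    reference_laps: pd.DataFrame,
    subject_id: str,
    lap_speeds: dict[int, float] | None = None,
) -> pd.DataFrame:
    """Long-format device-vs-reference table for the agreement models.

    ``device_laps`` comes from :func:`match_lap_segments` (columns lap,
    power, gct_ms, lss); ``reference_laps`` carries one row per lap of
    reference metrics (columns lap, power, gct_ms, lss, speed).  Output has
    one row per (lap, device, metric) observation; missing laps are simply
    absent.
    """
    if device_laps["lap"].duplicated().any() or reference_laps["lap"].duplicated().any():
        raise ValidationError("duplicate lap keys")
    rows = []
    speeds = lap_speeds or {}
    ref_by_lap = reference_laps.set_index("lap")
    dev_by_lap = device_laps.set_index("lap")
    for metric in ("power", "gct_ms", "lss"):
        for lap, ref_row in ref_by_lap.iterrows():
            if metric in ref_row and np.isfinite(ref_row[metric]):
                rows.append(
                    {
                        "subject": subject_id,
                        "lap": lap,
                        "speed": speeds.get(lap, ref_row.get("speed", np.nan)),
                        "device": "reference",
                        "metric": metric,
                        "value": float(ref_row[metric]),
                    }
                )
        for lap, dev_row in dev_by_lap.iterrows():
            if dev_row.get("n_samples", 1) and np.isfinite(dev_row[metric]):
                ref_speed = (
                    ref_by_lap["speed"].get(lap, np.nan)
                    if "speed" in ref_by_lap
                    else np.nan
                )
                rows.append(
                    {
                        "subject": subject_id,
                        "lap": lap,
                        "speed": speeds.get(lap, ref_speed),
                        "device": "pod",
                        "metric": metric,
                        "value": float(dev_row[metric]),
                    }
                )
    return pd.DataFrame(rows)


def standardise(values: np.ndarray) -> np.ndarray:
    """Z-score standardisation (population sd), as applied to covariates."""
    values = np.asarray(values, dtype=float)
    sd = values.std()
    if sd == 0:
        raise ValidationError("cannot standardise a constant column")
    return (values - values.mean()) / sd


def model_frame(comparison: pd.DataFrame, metric: str) -> pd.DataFrame:
    """Model-ready frame for one metric: y, device indicator, z-scored speed.

    Device is coded 0 for the reference system and 1 for the footpod, so
    the device coefficient reads as the pod-minus-reference offset.
    """
    sel = comparison[comparison["metric"] == metric].copy()
    if sel.empty:
        raise ValidationError(f"no rows for metric {metric!r}")
    sel["device_code"] = (sel["device"] == "pod").astype(float)
    sel["speed_z"] = standardise(sel["speed"].to_numpy())
    return sel.rename(columns={"value": "y"})[
        ["subject", "lap", "speed", "speed_z", "device_code", "y"]
    ].reset_index(drop=True)
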