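"""Multi-subject device-versus-reference statistics for one metric.

Fits the agreement mixed model and its reduced forms, derives the
term-wise Bayes factors by bridge sampling, the ICC, the Bland-Altman
limits of agreement, and (for power) the affine correction function.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .alignment import model_frame
from .bayes_compare import (
    BayesFactorResult,
    BlandAltmanResult,
    CorrectionResult,
    LmmFit,
    bayes_factor,
    bland_altman,
    correction_function,
    fit_lmm,
    icc,
)
from .grf_pipeline import ValidationError

#: Comparison-table metric name -> (model key for priors, scale applied to y).
#: Contact time is modelled in seconds, as reference methods report it.
METRIC_MODEL = {
    "power": ("power", 1.0),
    "gct_ms": ("gct", 1e-3),
    "lss": ("lss", 1.0),
}


@dataclass
class MetricComparison:
    metric: str
    fit_full: LmmFit
    fit_no_interaction: LmmFit
    bf_device: BayesFactorResult
    bf_speed: BayesFactorResult
    bf_interaction: BayesFactorResult
    icc: tuple[float, tuple[float, float]]
    bland_altman: BlandAltmanResult
    correction: CorrectionResult | None

    def summary_table(self) -> pd.DataFrame:
        """Posterior table of the full model with BF10 per tested term."""
        table = self.fit_full.summary.table.copy()
        table["BF10"] = np.nan
        table.loc["device", "BF10"] = self.bf_device.bf10
        table.loc["speed", "BF10"] = self.bf_speed.bf10
        if "device:speed" in table.index:
            table.loc["device:speed", "BF10"] = self.bf_interaction.bf10
        return table


def paired_values(
    comparison: pd.DataFrame, metric: str
) -> tuple[np.ndarray, np.ndarray]:
    """Reference/device value pairs matched on (subject, lap)."""
    sel = comparison[comparison["metric"] == metric]
    wide = sel.pivot_table(
        index=["subject", "lap"], columns="device", values="value"
    ).dropna()
    if wide.empty or not {"reference", "pod"}.issubset(wide.columns):
        raise ValidationError(f"no complete pairs for metric {metric!r}")
    return wide["reference"].to_numpy(), wide["pod"].to_numpy()


def per_speed_averages(
    comparison: pd.DataFrame, metric: str = "power", decimals: int = 2
) -> pd.DataFrame:
    """Device and reference means per (rounded) stage speed."""
    sel = comparison[comparison["metric"] == metric].copy()
    sel["speed_bin"] = sel["speed"].round(decimals)
    wide = sel.pivot_table(
        index="speed_bin", columns="device", values="value", aggfunc="mean"
    ).dropna()
    return wide.reset_index()


def compare_metric(
    comparison: pd.DataFrame,
    metric: str,
    seed: int = 0,
    sampler_kwargs: dict | None = None,
) -> MetricComparison:
    """Full agreement analysis of one metric across all subjects.

    Bayes factors compare models with and without a term: the device and
    speed factors are tested within the no-interaction model, the
    interaction by full versus no-interaction.
    """
    if metric not in METRIC_MODEL:
        raise ValidationError(f"unknown metric {metric!r}")
    model_key, y_scale = METRIC_MODEL[metric]
    frame = model_frame(comparison, metric)
    frame["y"] = frame["y"] * y_scale
    kw = dict(sampler_kwargs or {})

    fit_full = fit_lmm(frame, model_key, seed=seed, **kw)
    fit_ds = fit_lmm(frame, model_key, include_interaction=False, seed=seed + 1, **kw)
    fit_s = fit_lmm(
        frame, model_key, include_device=False, include_interaction=False,
        seed=seed + 2, **kw,
    )
    fit_d = fit_lmm(
        frame, model_key, include_speed=False, include_interaction=False,
        seed=seed + 3, **kw,
    )
    bf_device = bayes_factor(fit_ds, fit_s, seed=seed + 10)
    bf_speed = bayes_factor(fit_ds, fit_d, seed=seed + 11)
    bf_inter = bayes_factor(fit_full, fit_ds, seed=seed + 12)

    ref, dev = paired_values(comparison, metric)
    ba = bland_altman(ref * y_scale, dev * y_scale)
    corr = None
    if metric == "power":
        speed_avg = per_speed_averages(comparison, metric)
        if len(speed_avg) >= 2:
            corr = correction_function(
                speed_avg["reference"].to_numpy(), speed_avg["pod"].to_numpy()
            )
    return MetricComparison(
        metric=metric,
        fit_full=fit_full,
        fit_no_interaction=fit_ds,
        bf_device=bf_device,
        bf_speed=bf_speed,
        bf_interaction=bf_inter,
        icc=icc(fit_full),
        bland_altman=ba,
        correction=corr,
    )
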