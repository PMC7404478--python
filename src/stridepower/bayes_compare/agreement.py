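"""Bland-Altman agreement analysis and the linear power-correction function."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from ..grf_pipeline import ValidationError


@dataclass(frozen=True)
class BlandAltmanResult:
    """Bias and 1.96-sd limits of agreement for device minus reference."""

    bias: float
    sd: float
    loa_lower: float
    loa_upper: float
    bias_ci: tuple[float, float]
    loa_lower_ci: tuple[float, float]
    loa_upper_ci: tuple[float, float]
    proportional_slope: float   # slope of differences on pair means
    n: int


def bland_altman(reference: np.ndarray, device: np.ndarray) -> BlandAltmanResult:
    """Limits-of-agreement analysis of paired device/reference values.

    Differences are ``device - reference``.  Confidence intervals use the
    standard normal-theory formulas: t-based for the bias, and
    ``sd * sqrt(1/n + z^2 / (2(n-1)))`` for the standard error of each
    limit.  The proportional-error diagnostic is the least-squares slope of
    the differences on the pair means.
    """
    reference = np.asarray(reference, dtype=float)
    device = np.asarray(device, dtype=float)
    if reference.size != device.size:
        raise ValidationError("paired inputs must have equal length")
    n = reference.size
    if n < 3:
        raise ValidationError("need at least 3 pairs")
    diffs = device - reference
    means = (device + reference) / 2.0
    bias = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    z = 1.959963984540054
    loa_lo, loa_hi = bias - z * sd, bias + z * sd
    tcrit = float(stats.t.ppf(0.975, n - 1))
    se_bias = sd / np.sqrt(n)
    se_loa = sd * np.sqrt(1.0 / n + z * z / (2.0 * (n - 1)))
    slope = float(np.polyfit(means, diffs, 1)[0]) if np.ptp(means) > 0 else 0.0
    return BlandAltmanResult(
        bias=bias,
        sd=sd,
        loa_lower=float(loa_lo),
        loa_upper=float(loa_hi),
        bias_ci=(bias - tcrit * se_bias, bias + tcrit * se_bias),
        loa_lower_ci=(loa_lo - tcrit * se_loa, loa_lo + tcrit * se_loa),
        loa_upper_ci=(loa_hi - tcrit * se_loa, loa_hi + tcrit * se_loa),
        proportional_slope=slope,
        n=n,
    )


@dataclass(frozen=True)
class CorrectionResult:
    """Affine map from device power to reference power: ref ~ a * dev + b."""

    a: float
    b: float
    residual_rms: float
    n: int

    def apply(self, device_values: np.ndarray) -> np.ndarray:
        return self.a * np.asarray(device_values, dtype=float) + self.b


def correction_function(
    reference_po: np.ndarray, device_po: np.ndarray
) -> CorrectionResult:
    """Least-squares line mapping per-speed averaged device PO to reference PO.

    The coefficients are cohort-specific descriptive corrections, not
    universal constants; residual RMS quantifies how affine the device
    error actually is.
    """
    reference_po = np.asarray(reference_po, dtype=float)
    device_po = np.asarray(device_po, dtype=float)
    if reference_po.size != device_po.size or reference_po.size < 2:
        raise ValidationError("need >= 2 paired per-speed averages")
    if np.ptp(device_po) == 0:
        raise ValidationError("constant device power: correction unidentifiable")
    a, b = np.polyfit(device_po, reference_po, 1)
    resid = reference_po - (a * device_po + b)
    return CorrectionResult(
        a=float(a),
        b=float(b),
        residual_rms=float(np.sqrt(np.mean(resid**2))),
        n=reference_po.size,
    )
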