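"""Bayesian Pearson correlation with a non-informative prior on rho.

Uses the exact reduced likelihood of the sample correlation r given the
population correlation rho (Jeffreys' integral, hypergeometric form):

    p(r | rho) propto (1 - rho^2)^((n-1)/2) (1 - rho r)^((3-2n)/2)
                      2F1(1/2, 1/2; n - 1/2; (1 + rho r)/2),

combined with the uniform (stretched-beta, kappa = 1) prior on (-1, 1).
Posterior summaries and the Bayes factor against rho = 0 come from direct
grid integration in log space -- deterministic and fast.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import hyp2f1

from ..grf_pipeline import ValidationError


@dataclass(frozen=True)
class CorrelationResult:
    r_observed: float
    n: int
    rho_median: float
    ci: tuple[float, float]
    bf10: float

    def posterior(self) -> tuple[np.ndarray, np.ndarray]:
        return _posterior_grid(self.r_observed, self.n)


def _log_reduced_likelihood(rho: np.ndarray, r: float, n: int) -> np.ndarray:
    with np.errstate(divide="ignore"):
        out = (
            (n - 1) / 2.0 * np.log1p(-rho * rho)
            + (3.0 - 2.0 * n) / 2.0 * np.log1p(-rho * r)
            + np.log(hyp2f1(0.5, 0.5, n - 0.5, (1.0 + rho * r) / 2.0))
        )
    return out


def _posterior_grid(r: float, n: int, m: int = 4001) -> tuple[np.ndarray, np.ndarray]:
    rho = np.linspace(-0.99995, 0.99995, m)
    logp = _log_reduced_likelihood(rho, r, n)
    logp -= logp.max()
    dens = np.exp(logp)
    dens /= np.trapezoid(dens, rho)
    return rho, dens


def bayesian_correlation(x: np.ndarray, y: np.ndarray) -> CorrelationResult:
    """Posterior over the Pearson correlation and BF10 against rho = 0."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 4:
        raise ValidationError("need n >= 4 paired observations")
    if x.std() == 0 or y.std() == 0:
        raise ValidationError("zero-variance input")
    n = x.size
    r = float(np.corrcoef(x, y)[0, 1])
    r = float(np.clip(r, -0.999999, 0.999999))

    rho, dens = _posterior_grid(r, n)
    cdf = np.concatenate([[0.0], np.cumsum((dens[1:] + dens[:-1]) / 2 * np.diff(rho))])
    cdf /= cdf[-1]
    median = float(np.interp(0.5, cdf, rho))
    lo = float(np.interp(0.025, cdf, rho))
    hi = float(np.interp(0.975, cdf, rho))

    # BF10: uniform-prior average of the likelihood over rho versus rho = 0
    logp = _log_reduced_likelihood(rho, r, n)
    ref = logp.max()
    marg = np.trapezoid(np.exp(logp - ref), rho) / 2.0  # prior density 1/2
    log_bf = np.log(marg) + ref - _log_reduced_likelihood(np.array([0.0]), r, n)[0]
    return CorrelationResult(
        r_observed=r, n=n, rho_median=median, ci=(lo, hi), bf10=float(np.exp(log_bf))
    )
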