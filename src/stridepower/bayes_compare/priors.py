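"""Prior specifications for the agreement models.

Fixed-effect priors follow the validation study design: a fat-tailed
Student-t(3, 0, 10) on the intercept, a metric-specific Gaussian on the
device offset (very vague for power, where the offset scale was unknown a
priori), and a weakly informative Gaussian on the speed slope.  The
interaction term, for which no scale was stated, inherits the speed-term
prior of its metric.  Scale parameters get half-Student-t(3) priors with
scale 2.5 sd(y); the random intercept-slope correlation gets an LKJ(2)
marginal.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import lgamma, log, pi

import numpy as np


@dataclass(frozen=True)
class PriorSpec:
    """One univariate prior: ``normal`` or ``student_t`` (df, loc, scale)."""

    dist: str
    loc: float
    scale: float
    df: float | None = None

    def __post_init__(self) -> None:
        if self.dist not in ("normal", "student_t"):
            raise ValueError(f"unknown prior family {self.dist!r}")
        if self.scale <= 0:
            raise ValueError("prior scale must be positive")
        if self.dist == "student_t" and (self.df is None or self.df <= 0):
            raise ValueError("student_t prior needs positive df")

    def logpdf(self, x: np.ndarray) -> np.ndarray:
        z = (np.asarray(x, dtype=float) - self.loc) / self.scale
        if self.dist == "normal":
            return -0.5 * z * z - 0.5 * log(2 * pi) - log(self.scale)
        nu = float(self.df)
        const = (
            lgamma((nu + 1) / 2) - lgamma(nu / 2) - 0.5 * log(nu * pi) - log(self.scale)
        )
        return const - (nu + 1) / 2 * np.log1p(z * z / nu)

    def half_logpdf(self, x: np.ndarray) -> np.ndarray:
        """Log density of the distribution folded at zero (for scales)."""
        x = np.asarray(x, dtype=float)
        out = self.logpdf(x) + log(2.0)
        return np.where(x > 0, out, -np.inf)


def normal(scale: float, loc: float = 0.0) -> PriorSpec:
    return PriorSpec("normal", loc, scale)


def student_t(df: float, loc: float, scale: float) -> PriorSpec:
    return PriorSpec("student_t", loc, scale, df)


#: Fixed-effect priors per metric, ordered (intercept, device, speed,
#: device x speed).  Response units: W for power, s for contact time,
#: kN/m for leg-spring stiffness.
DEFAULT_FIXED_PRIORS: dict[str, tuple[PriorSpec, PriorSpec, PriorSpec, PriorSpec]] = {
    "power": (student_t(3, 0, 10), normal(1000), normal(200), normal(200)),
    "gct": (student_t(3, 0, 10), normal(1), normal(1), normal(1)),
    "lss": (student_t(3, 0, 10), normal(10), normal(1), normal(1)),
}

#: Simple-regression priors (intercept, slope).
DEFAULT_SIMPLE_PRIORS: tuple[PriorSpec, PriorSpec] = (
    student_t(3, 0, 10),
    normal(10),
)

#: Multiplier on sd(y) for the half-t(3) priors on sigma and random-effect
#: standard deviations.
SD_PRIOR_MULT = 2.5

#: LKJ shape for the bivariate random-effect correlation; eta = 2 gives the
#: marginal density 0.75 (1 - rho^2) on (-1, 1).
LKJ_ETA = 2.0


def lkj_marginal_logpdf(rho: np.ndarray, eta: float = LKJ_ETA) -> np.ndarray:
    """Normalised log density of the bivariate LKJ marginal correlation."""
    from scipy.special import betaln

    rho = np.asarray(rho, dtype=float)
    # (1-rho^2)^(eta-1) on (-1,1), normalising via the Beta(eta, eta) kernel
    lognorm = betaln(eta, eta) + (2 * eta - 1) * log(2.0)
    out = (eta - 1) * np.log1p(-rho * rho) - lognorm
    return np.where(np.abs(rho) < 1, out, -np.inf)
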