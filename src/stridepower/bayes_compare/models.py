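"""Bayesian simple and mixed linear models, sampled with ensemble MCMC.

The device-agreement model is

    y_ijk = b0 + S0_i + b1 device_k + (b2 + S1_i) speed_j
            + b3 (speed_j device_k) + e_ijk,

with per-subject random intercepts and speed slopes (S0_i, S1_i) drawn from
a bivariate normal with standard deviations (tau0, tau1) and correlation
rho.  The random effects are integrated out analytically (each subject's
marginal covariance is sigma^2 I + Z Sigma_b Z', handled by the Woodbury
identity on 2x2 blocks), which leaves a low-dimensional posterior over
(betas, log tau0, log tau1, atanh-type rho transform, log sigma) that an
affine-invariant ensemble sampler traverses quickly.  The fully normalised
log joint is exposed so bridge sampling can estimate marginal likelihoods.

Split-R-hat and effective sample sizes are computed with arviz, treating
ensemble walkers as chains.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import log, pi

import arviz as az
import emcee
import numpy as np
import pandas as pd

from ..grf_pipeline import ValidationError
from .priors import (
    DEFAULT_FIXED_PRIORS,
    DEFAULT_SIMPLE_PRIORS,
    LKJ_ETA,
    SD_PRIOR_MULT,
    PriorSpec,
    lkj_marginal_logpdf,
    student_t,
)

_LOG2PI = log(2 * pi)
_RHAT_LIMIT = 1.01


@dataclass
class PosteriorSummary:
    """Posterior table plus convergence diagnostics for one fitted model."""

    table: pd.DataFrame           # Estimate, Est.Error, CI_lower, CI_upper
    rhat: dict[str, float]
    ess: dict[str, float]
    converged: bool
    seed: int
    sampler_settings: dict


def _diagnostics(
    natural: np.ndarray, names: list[str], n_runs: int
) -> tuple[dict, dict, bool]:
    """R-hat and bulk ESS per parameter.

    ``natural`` has shape (draw, walker*runs, dim).  ESS always treats each
    walker trajectory as a chain (preserving within-walker autocorrelation);
    R-hat is computed across independent runs when more than one was made,
    since ensemble walkers are interacting and their split-R-hat converges
    slowly even after the ensemble has equilibrated.
    """
    n_draw, n_wr, ndim = natural.shape
    walker_chains = {nm: natural[:, :, i].T for i, nm in enumerate(names)}
    ess = {k: float(v.values) for k, v in az.ess(az.from_dict(posterior=walker_chains)).items()}
    if n_runs > 1:
        w = n_wr // n_runs
        per_run = natural.reshape(n_draw, n_runs, w, ndim)
        run_chains = {
            nm: per_run[:, :, :, i].transpose(1, 0, 2).reshape(n_runs, -1)
            for i, nm in enumerate(names)
        }
        rhat_src = run_chains
    else:
        rhat_src = walker_chains
    rhat = {k: float(v.values) for k, v in az.rhat(az.from_dict(posterior=rhat_src)).items()}
    finite = [v for v in rhat.values() if np.isfinite(v)]
    converged = bool(finite) and max(finite) <= _RHAT_LIMIT
    return rhat, ess, converged


def _data_intercept_prior(y: np.ndarray) -> PriorSpec:
    """Vague intercept prior anchored at the response median.

    student_t(3, median(y), max(2.5, mad(y))), the default of the Stan
    regression front ends that centre their design matrices.
    """
    med = float(np.median(y))
    mad = float(np.median(np.abs(y - med))) * 1.4826
    return student_t(3, med, max(2.5, mad))


def _sample_ensembles(
    log_post,
    start: np.ndarray,
    spread: np.ndarray,
    seed: int,
    n_walkers: int,
    n_burn: int,
    n_draws: int,
    n_runs: int,
) -> np.ndarray:
    """Run ``n_runs`` independent DE ensembles; stack on the walker axis.

    Returns an array of shape (n_draws, n_walkers * n_runs, ndim).  The
    initial cloud is overdispersed to the posterior's expected width, since
    differential-evolution proposals scale with the ensemble spread.
    """
    ndim = start.size
    chains = []
    for k in range(n_runs):
        run_seed = seed + 9973 * k
        rng = np.random.default_rng(run_seed)
        p0 = start + rng.normal(size=(n_walkers, ndim)) * spread
        moves = [(emcee.moves.DEMove(), 0.8), (emcee.moves.DESnookerMove(), 0.2)]
        sampler = emcee.EnsembleSampler(
            n_walkers, ndim, log_post, vectorize=True, moves=moves
        )
        sampler.random_state = np.random.RandomState(run_seed).get_state()
        sampler.run_mcmc(p0, n_burn + n_draws, progress=False)
        chains.append(sampler.get_chain(discard=n_burn))
    return np.concatenate(chains, axis=1)


def _summary_row(draws: np.ndarray) -> list[float]:
    lo, hi = np.percentile(draws, [2.5, 97.5])
    return [float(draws.mean()), float(draws.std(ddof=1)), float(lo), float(hi)]


# ---------------------------------------------------------------------------
# simple linear regression


@dataclass
class SimpleLinearFit:
    """Posterior of ``y = b0 + b1 x + e`` with posterior-predictive R^2."""

    x: np.ndarray
    y: np.ndarray
    beta_draws: np.ndarray        # (N, 2)
    sigma_draws: np.ndarray       # (N,)
    r2_draws: np.ndarray          # (N,)
    summary: PosteriorSummary
    _theta_chain: np.ndarray = field(repr=False)      # (N, 3) for bridge
    _log_post: object = field(repr=False)

    @property
    def converged(self) -> bool:
        return self.summary.converged

    def r2(self) -> tuple[float, tuple[float, float]]:
        lo, hi = np.percentile(self.r2_draws, [2.5, 97.5])
        return float(np.median(self.r2_draws)), (float(lo), float(hi))


def fit_simple_linear(
    y: np.ndarray,
    x: np.ndarray,
    priors: tuple[PriorSpec, PriorSpec] | None = None,
    include_slope: bool = True,
    center_intercept_prior: bool = True,
    seed: int = 0,
    n_walkers: int = 24,
    n_burn: int = 500,
    n_draws: int = 700,
    n_runs: int = 1,
) -> SimpleLinearFit:
    """Sample the posterior of a Bayesian simple linear regression.

    The slope prior defaults to the weakly informative N(0, 10); sigma gets
    a half-t(3, 0, 2.5 sd(y)).  ``include_slope=False`` fits the
    intercept-only null, for Bayes-factor comparisons.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if y.size < 3 or x.size != y.size:
        raise ValidationError("need n >= 3 paired finite observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValidationError("non-finite data")
    priors = priors or DEFAULT_SIMPLE_PRIORS
    if center_intercept_prior:
        priors = (_data_intercept_prior(y), priors[1])
    sd_y = max(y.std(), 1e-12)
    sigma_prior = student_t(3, 0, SD_PRIOR_MULT * sd_y)
    n = y.size
    p = 2 if include_slope else 1

    def log_post(theta: np.ndarray) -> np.ndarray:
        theta = np.atleast_2d(theta)
        b0 = theta[:, 0]
        b1 = theta[:, 1] if include_slope else 0.0
        log_s = theta[:, p]
        ok = np.abs(log_s) < 15
        s = np.exp(np.clip(log_s, -15, 15))
        mu = b0[:, None] + (np.outer(b1, x) if include_slope else 0.0)
        resid2 = ((y[None, :] - mu) ** 2).sum(axis=1)
        ll = -0.5 * (n * _LOG2PI + 2 * n * log_s + resid2 / (s * s))
        lp = priors[0].logpdf(b0)
        if include_slope:
            lp = lp + priors[1].logpdf(theta[:, 1])
        lp = lp + sigma_prior.half_logpdf(s) + log_s  # jacobian of log-scale
        out = ll + lp
        return np.where(ok, out, -np.inf)

    slope0, inter0 = (np.polyfit(x, y, 1) if include_slope else (0.0, y.mean()))
    resid = y - (inter0 + slope0 * x)
    resid_sd = max(resid.std(), 1e-6)
    se_slope = resid_sd / max(np.sqrt(n) * x.std(), 1e-9)
    start = np.asarray(
        [inter0] + ([slope0] if include_slope else []) + [log(resid_sd)]
    )
    spread = np.asarray(
        [3 * resid_sd / np.sqrt(n) + 1e-3]
        + ([3 * se_slope + 1e-4] if include_slope else [])
        + [0.4]
    )
    chain = _sample_ensembles(
        log_post, start, spread, seed, n_walkers, n_burn, n_draws, n_runs
    )

    names = ["Intercept"] + (["slope"] if include_slope else []) + ["sigma"]
    natural = np.concatenate(
        [chain[:, :, :p], np.exp(chain[:, :, p:])], axis=2
    )
    rhat, ess, converged = _diagnostics(natural, names, n_runs)
    flat = natural.reshape(-1, p + 1)
    beta = np.column_stack([flat[:, 0], flat[:, 1] if include_slope else np.zeros(len(flat))])
    sigma = flat[:, p]
    var_fit = beta[:, 1] ** 2 * x.var()  # fitted-value variance, exactly
    r2 = var_fit / (var_fit + sigma**2)
    table = pd.DataFrame(
        [_summary_row(flat[:, i]) for i in range(p + 1)],
        index=names,
        columns=["Estimate", "Est.Error", "CI_lower", "CI_upper"],
    )
    summary = PosteriorSummary(
        table=table,
        rhat=rhat,
        ess=ess,
        converged=converged,
        seed=seed,
        sampler_settings={"walkers": n_walkers, "burn": n_burn, "draws": n_draws},
    )
    return SimpleLinearFit(
        x=x,
        y=y,
        beta_draws=beta,
        sigma_draws=sigma,
        r2_draws=r2,
        summary=summary,
        _theta_chain=chain.reshape(-1, p + 1),
        _log_post=log_post,
    )


# ---------------------------------------------------------------------------
# linear mixed model


@dataclass
class LmmFit:
    """Posterior of the device-agreement mixed model for one metric."""

    terms: list[str]                  # fixed-effect column names
    draws: dict[str, np.ndarray]      # natural-scale draws per parameter
    summary: PosteriorSummary
    n_obs: int
    n_subjects: int
    _theta_chain: np.ndarray = field(repr=False)
    _log_post: object = field(repr=False)

    @property
    def converged(self) -> bool:
        return self.summary.converged

    def fixed_effect(self, term: str) -> tuple[float, tuple[float, float]]:
        d = self.draws[term]
        lo, hi = np.percentile(d, [2.5, 97.5])
        return float(d.mean()), (float(lo), float(hi))

    def icc_draws(self) -> np.ndarray:
        """Per-draw ICC at the covariate reference point (speed_z = 0):
        tau0^2 / (tau0^2 + sigma^2); the random-slope variance drops out
        there."""
        t0 = self.draws["sd_intercept"]
        s = self.draws["sigma"]
        return t0**2 / (t0**2 + s**2)


def _subject_blocks(frame: pd.DataFrame, cols: list[str]) -> list[dict]:
    blocks = []
    for _, sub in frame.groupby("subject", sort=True):
        X = np.column_stack(
            [
                np.ones(len(sub))
                if c == "Intercept"
                else sub["device_code"].to_numpy()
                if c == "device"
                else sub["speed_z"].to_numpy()
                if c == "speed"
                else sub["device_code"].to_numpy() * sub["speed_z"].to_numpy()
                for c in cols
            ]
        )
        Z = np.column_stack([np.ones(len(sub)), sub["speed_z"].to_numpy()])
        yv = sub["y"].to_numpy(dtype=float)
        blocks.append(
            {
                "n": len(sub),
                "yty": float(yv @ yv),
                "Xty": X.T @ yv,
                "XtX": X.T @ X,
                "Zty": Z.T @ yv,
                "ZtX": Z.T @ X,
                "ZtZ": Z.T @ Z,
            }
        )
    return blocks


def fit_lmm(
    frame: pd.DataFrame,
    metric: str = "power",
    priors: tuple[PriorSpec, ...] | None = None,
    include_device: bool = True,
    include_speed: bool = True,
    include_interaction: bool = True,
    center_intercept_prior: bool = True,
    seed: int = 0,
    n_walkers: int = 32,
    n_burn: int = 700,
    n_draws: int = 800,
    n_runs: int = 1,
) -> LmmFit:
    """Sample the device-agreement LMM posterior for one metric.

    ``frame`` needs columns ``subject, y, device_code, speed_z`` (speed
    already standardised).  Missing laps and unbalanced designs are handled
    naturally since each subject contributes its own block.  Dropping the
    device (or interaction) term yields the reduced models used in the
    Bayes-factor comparisons.
    """
    required = {"subject", "y", "device_code", "speed_z"}
    if not required.issubset(frame.columns):
        raise ValidationError(f"model frame must contain columns {sorted(required)}")
    if frame["subject"].nunique() < 2:
        raise ValidationError("random effects need at least two subjects")
    if priors is None:
        priors = DEFAULT_FIXED_PRIORS.get(metric, DEFAULT_FIXED_PRIORS["power"])
    if center_intercept_prior:
        # data-anchored intercept prior: student_t(3, median(y),
        # max(2.5, mad(y))).  A fixed-location, narrow intercept prior far
        # below the response level would push the intercept into the random
        # effects and leave a spurious ridge along (intercept, tau0); the
        # data-dependent anchor is the convention of mixed-model stacks
        # that centre their design matrices
        priors = (_data_intercept_prior(frame["y"].to_numpy()),) + tuple(priors[1:])

    cols = ["Intercept"]
    prior_list = [priors[0]]
    if include_device:
        cols.append("device")
        prior_list.append(priors[1])
    if include_speed:
        cols.append("speed")
        prior_list.append(priors[2])
    if include_interaction:
        if not (include_device and include_speed):
            raise ValidationError("interaction requires the device and speed terms")
        cols.append("device:speed")
        prior_list.append(priors[3])
    p = len(cols)
    ndim = p + 4

    blocks = _subject_blocks(frame, cols)
    yv = frame["y"].to_numpy(dtype=float)
    sd_y = max(yv.std(), 1e-12)
    scale_prior = student_t(3, 0, SD_PRIOR_MULT * sd_y)
    n_total = len(frame)

    XtX = np.sum([b["XtX"] for b in blocks], axis=0)
    Xty = np.sum([b["Xty"] for b in blocks], axis=0)

    # stack per-subject sufficient statistics for full vectorisation
    ns = np.asarray([b["n"] for b in blocks], dtype=float)         # (S,)
    yty_s = np.asarray([b["yty"] for b in blocks])                 # (S,)
    Xty_s = np.asarray([b["Xty"] for b in blocks])                 # (S, p)
    XtX_s = np.asarray([b["XtX"] for b in blocks])                 # (S, p, p)
    Zty_s = np.asarray([b["Zty"] for b in blocks])                 # (S, 2)
    ZtX_s = np.asarray([b["ZtX"] for b in blocks])                 # (S, 2, p)
    A_s = np.asarray([b["ZtZ"] for b in blocks])                   # (S, 2, 2)
    A00, A01 = A_s[:, 0, 0], A_s[:, 0, 1]
    A10, A11 = A_s[:, 1, 0], A_s[:, 1, 1]

    def log_post(theta: np.ndarray) -> np.ndarray:
        theta = np.atleast_2d(theta)
        with np.errstate(all="ignore"):
            return _log_post_impl(theta)

    def _log_post_impl(theta: np.ndarray) -> np.ndarray:
        beta = theta[:, :p]                               # (W, p)
        lt0, lt1, w_r, ls = (theta[:, p + i] for i in range(4))
        bad = (
            (np.abs(lt0) > 15) | (np.abs(lt1) > 15) | (np.abs(ls) > 15)
            | (np.abs(w_r) > 12)
        )
        t0 = np.exp(np.clip(lt0, -15, 15))[:, None]       # (W, 1)
        t1 = np.exp(np.clip(lt1, -15, 15))[:, None]
        s = np.exp(np.clip(ls, -15, 15))[:, None]
        rho = np.tanh(w_r)[:, None]
        s2 = s * s
        det_b = t0 * t0 * t1 * t1 * (1 - rho * rho) + 1e-300
        c01 = rho * t0 * t1
        u0 = Zty_s[None, :, 0] - np.einsum("sp,wp->ws", ZtX_s[:, 0], beta)
        u1 = Zty_s[None, :, 1] - np.einsum("sp,wp->ws", ZtX_s[:, 1], beta)
        rtr = (
            yty_s[None, :]
            - 2.0 * np.einsum("sp,wp->ws", Xty_s, beta)
            + np.einsum("wp,spq,wq->ws", beta, XtX_s, beta)
        )
        # logdet(I + Sigma_b A / s^2) via 2x2 closed form, (W, S)
        B00 = (t0 * t0 * A00 + c01 * A10) / s2
        B01 = (t0 * t0 * A01 + c01 * A11) / s2
        B10 = (c01 * A00 + t1 * t1 * A10) / s2
        B11 = (c01 * A01 + t1 * t1 * A11) / s2
        det_term = (1 + B00) * (1 + B11) - B01 * B10
        # M = Sigma_b^-1 + A/s^2
        M00 = t1 * t1 / det_b + A00 / s2
        M11 = t0 * t0 / det_b + A11 / s2
        M01 = -c01 / det_b + A01 / s2
        detM = M00 * M11 - M01 * M01
        quad = (M11 * u0 * u0 - 2 * M01 * u0 * u1 + M00 * u1 * u1) / detM
        ll = -0.5 * (
            ns[None, :] * (_LOG2PI + 2 * ls[:, None])
            + np.log(np.maximum(det_term, 1e-300))
            + rtr / s2
            - quad / (s2 * s2)
        ).sum(axis=1)
        rho = rho[:, 0]
        t0, t1, s = t0[:, 0], t1[:, 0], s[:, 0]
        lp = np.zeros(theta.shape[0])
        for j, pr in enumerate(prior_list):
            lp += pr.logpdf(beta[:, j])
        lp += scale_prior.half_logpdf(t0) + lt0
        lp += scale_prior.half_logpdf(t1) + lt1
        lp += scale_prior.half_logpdf(s) + ls
        lp += lkj_marginal_logpdf(rho, LKJ_ETA) + np.log1p(-rho * rho)  # tanh jac
        out = ll + lp
        return np.where(bad | ~np.isfinite(out), -np.inf, out)

    # data-driven, overdispersed initialisation: differential-evolution moves
    # scale their proposals by the ensemble spread, so the starting cloud
    # must already cover the posterior's width
    beta_hat, *_ = np.linalg.lstsq(XtX, Xty, rcond=None)
    resid_var = max(
        (yv @ yv - beta_hat @ Xty) / max(n_total - p, 1), 1e-12
    )
    se_beta = np.sqrt(
        np.diag(np.linalg.pinv(XtX)) * resid_var
    )
    start = np.r_[
        beta_hat,
        log(max(0.5 * np.sqrt(resid_var), 1e-4)),
        log(max(0.25 * np.sqrt(resid_var), 1e-4)),
        0.0,
        0.5 * log(resid_var),
    ]
    spread = np.r_[3.0 * se_beta + 1e-3, 0.8, 0.8, 0.6, 0.3]
    chain = _sample_ensembles(
        log_post, start, spread, seed, n_walkers, n_burn, n_draws, n_runs
    )

    names = cols + ["sd_intercept", "sd_slope", "cor_intercept_speed", "sigma"]
    natural = np.concatenate(
        [
            chain[:, :, :p],
            np.exp(chain[:, :, p : p + 2]),
            np.tanh(chain[:, :, p + 2 : p + 3]),
            np.exp(chain[:, :, p + 3 : p + 4]),
        ],
        axis=2,
    )
    rhat, ess, converged = _diagnostics(natural, names, n_runs)
    flat = natural.reshape(-1, ndim)
    draws = {nm: flat[:, i] for i, nm in enumerate(names)}
    table = pd.DataFrame(
        [_summary_row(flat[:, i]) for i in range(ndim)],
        index=names,
        columns=["Estimate", "Est.Error", "CI_lower", "CI_upper"],
    )
    summary = PosteriorSummary(
        table=table,
        rhat=rhat,
        ess=ess,
        converged=converged,
        seed=seed,
        sampler_settings={"walkers": n_walkers, "burn": n_burn, "draws": n_draws},
    )
    return LmmFit(
        terms=cols,
        draws=draws,
        summary=summary,
        n_obs=n_total,
        n_subjects=frame["subject"].nunique(),
        _theta_chain=chain.reshape(-1, ndim),
        _log_post=log_post,
    )


# ---------------------------------------------------------------------------
# ICC


def icc_from_variances(var_subject: float, var_residual: float) -> float:
    """Intraclass correlation: between-subject over total variance."""
    if var_subject < 0 or var_residual < 0 or var_subject + var_residual == 0:
        raise ValidationError("variance components must be non-negative, not both zero")
    return var_subject / (var_subject + var_residual)


def icc(fit: LmmFit) -> tuple[float, tuple[float, float]]:
    """Posterior median ICC with 95% credible interval.

    Evaluated at standardised speed 0, where the random-slope contribution
    to the between-subject variance vanishes.
    """
    if "sd_intercept" not in fit.draws or "sigma" not in fit.draws:
        raise ValidationError("fit lacks variance components")
    d = fit.icc_draws()
    lo, hi = np.percentile(d, [2.5, 97.5])
    return float(np.median(d)), (float(lo), float(hi))


# ---------------------------------------------------------------------------
# design simulator for the statistical machinery


def simulate_mixed_design(
    n_subjects: int = 6,
    n_laps: int = 20,
    beta: tuple[float, float, float, float] = (570.0, -300.0, 65.0, -24.0),
    tau0: float = 86.0,
    tau1: float = 17.0,
    rho: float = 0.35,
    sigma: float = 50.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Data drawn exactly from the agreement LMM, for recovery checks.

    Every subject runs ``n_laps`` laps at linearly increasing speeds,
    measured by both devices; speeds enter standardised, the device is
    coded 0/1.  Defaults mirror the magnitude regime of a six-runner
    incremental-power validation (intercept ~570 W, device offset -300 W,
    residual sd ~50 W).
    """
    rng = np.random.default_rng(seed)
    speed_z = np.linspace(-1.0, 1.0, n_laps)
    speed_z = (speed_z - speed_z.mean()) / speed_z.std()
    cov = np.array(
        [[tau0**2, rho * tau0 * tau1], [rho * tau0 * tau1, tau1**2]]
    )
    b = rng.multivariate_normal(np.zeros(2), cov, size=n_subjects)
    rows = []
    for i in range(n_subjects):
        for j, sz in enumerate(speed_z):
            for dev in (0.0, 1.0):
                mu = (
                    beta[0]
                    + b[i, 0]
                    + beta[1] * dev
                    + (beta[2] + b[i, 1]) * sz
                    + beta[3] * sz * dev
                )
                rows.append(
                    {
                        "subject": f"S{i:02d}",
                        "lap": j,
                        "speed_z": sz,
                        "device_code": dev,
                        "y": mu + rng.normal(0, sigma),
                    }
                )
    return pd.DataFrame(rows)
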