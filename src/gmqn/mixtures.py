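"""Deterministic univariate EM fitters.

Two models are fitted in this package:

* a two-component Gaussian mixture on raw (non-log) signal intensities —
  the pooled intensities of one color channel of the Infinium I probes
  decompose into a low-mean "dark" peak (the silent bead of a site whose
  methylation is near 0 or 1) and a broad high-mean "lit" peak;
* a three-component beta mixture on beta-values (BMIQ's unmethylated /
  hemimethylated / methylated states, labelled U/H/M).

Both fitters are deterministic: initialization is quantile-based, there are
no random restarts, and identical inputs give bit-identical outputs.
Convergence is declared when the mean per-observation log-likelihood change
drops below ``tol``; this criterion is invariant under affine rescaling of
the data, which the between-array normalization relies on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import betaln, digamma, logsumexp, ndtr, ndtri

from .errors import ComponentCollapseError, DegenerateDataError, ParameterError, ValidationError

__all__ = [
    "GaussianComponent",
    "ChannelMixture",
    "BetaComponent",
    "BetaMixture3",
    "fit_gmm2",
    "fit_beta_mixture3",
    "gaussian_cdf",
    "gaussian_quantile",
]

_LOG_2PI = float(np.log(2.0 * np.pi))

#: Fallback beta shapes used when an initial U/H/M group is nearly empty.
PRIOR_BETA_SHAPES = {"U": (2.0, 18.0), "H": (5.0, 5.0), "M": (18.0, 2.0)}


@dataclass(frozen=True)
class GaussianComponent:
    mean: float
    sd: float
    weight: float

    def __post_init__(self):
        if self.sd <= 0:
            raise ParameterError(f"component sd must be positive, got {self.sd}")


@dataclass
class ChannelMixture:
    """Ordered two-state Gaussian mixture for one color channel.

    ``state1`` has the smaller mean (the dark peak), ``state2`` the larger.
    """

    state1: GaussianComponent
    state2: GaussianComponent
    channel: str | None = None
    loglik: float = float("nan")
    n_iter: int = 0
    converged: bool = False
    loglik_path: list[float] = field(default_factory=list, repr=False)

    def __post_init__(self):
        if not self.state1.mean < self.state2.mean:
            raise ParameterError(
                f"state1.mean ({self.state1.mean}) must be < state2.mean ({self.state2.mean})"
            )
        if abs(self.state1.weight + self.state2.weight - 1.0) > 1e-12:
            raise ParameterError("component weights must sum to 1")

    @property
    def means(self) -> np.ndarray:
        return np.array([self.state1.mean, self.state2.mean])

    @property
    def sds(self) -> np.ndarray:
        return np.array([self.state1.sd, self.state2.sd])

    @property
    def weights(self) -> np.ndarray:
        return np.array([self.state1.weight, self.state2.weight])


@dataclass(frozen=True)
class BetaComponent:
    a: float
    b: float
    weight: float

    @property
    def mean(self) -> float:
        return self.a / (self.a + self.b)


@dataclass
class BetaMixture3:
    """Three-component beta mixture with states labelled U < H < M by mean."""

    U: BetaComponent
    H: BetaComponent
    M: BetaComponent
    loglik: float = float("nan")
    n_iter: int = 0
    converged: bool = False
    loglik_path: list[float] = field(default_factory=list, repr=False)

    def __post_init__(self):
        means = [self.U.mean, self.H.mean, self.M.mean]
        if not (means[0] < means[1] < means[2]):
            raise ParameterError(f"component means must be increasing U<H<M, got {means}")
        total = self.U.weight + self.H.weight + self.M.weight
        if abs(total - 1.0) > 1e-12:
            raise ParameterError("component weights must sum to 1")

    @property
    def components(self) -> dict[str, BetaComponent]:
        return {"U": self.U, "H": self.H, "M": self.M}

    @property
    def shapes(self) -> np.ndarray:
        return np.array([[self.U.a, self.U.b], [self.H.a, self.H.b], [self.M.a, self.M.b]])

    @property
    def weights(self) -> np.ndarray:
        return np.array([self.U.weight, self.H.weight, self.M.weight])


# ---------------------------------------------------------------------------
# Gaussian helpers


def gaussian_cdf(x, comp: GaussianComponent):
    """CDF of N(comp.mean, comp.sd**2) at x."""
    if comp.sd <= 0:
        raise ParameterError("sd must be positive")
    return ndtr((np.asarray(x, float) - comp.mean) / comp.sd)


def gaussian_quantile(p, comp: GaussianComponent):
    """Quantile of N(comp.mean, comp.sd**2); p clamped to [1e-10, 1-1e-10]."""
    if comp.sd <= 0:
        raise ParameterError("sd must be positive")
    p = np.clip(np.asarray(p, float), 1e-10, 1.0 - 1e-10)
    return comp.mean + comp.sd * ndtri(p)


# ---------------------------------------------------------------------------
# Two-component Gaussian EM


def _gmm2_log_densities(x, means, sds, weights):
    z = (x[None, :] - means[:, None]) / sds[:, None]
    return (
        np.log(weights)[:, None]
        - np.log(sds)[:, None]
        - 0.5 * _LOG_2PI
        - 0.5 * z * z
    )


def fit_gmm2(
    values,
    tol: float = 1e-6,
    max_iter: int = 1000,
    channel: str | None = None,
) -> ChannelMixture:
    """Fit a two-component Gaussian mixture by EM, deterministically.

    Components are initialized from the halves of the data below/above the
    median (means at the 25th/75th percentiles, within-half standard
    deviations, equal weights) and returned sorted by mean.  The EM
    log-likelihood trace is kept on the result for audit; it is
    non-decreasing by construction.
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    n = x.size
    if n < 50:
        raise DegenerateDataError(f"need >= 50 finite values, got {n}")
    data_range = float(x.max() - x.min())
    if data_range <= 0 or float(np.var(x)) <= 0:
        raise DegenerateDataError("constant input: sample variance is zero")
    sd_floor = 1e-8 * data_range

    med = np.median(x)
    lo, hi = x[x <= med], x[x > med]
    means = np.array([np.percentile(x, 25.0), np.percentile(x, 75.0)])
    fallback_sd = max(float(np.std(x)) / 2.0, sd_floor * 10)
    sds = np.array(
        [
            float(np.std(lo)) if lo.size > 1 and np.std(lo) > 0 else fallback_sd,
            float(np.std(hi)) if hi.size > 1 and np.std(hi) > 0 else fallback_sd,
        ]
    )
    weights = np.array([0.5, 0.5])
    if means[0] == means[1]:
        means = means + np.array([-0.25, 0.25]) * float(np.std(x))

    path: list[float] = []
    ll_prev = -np.inf
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        logp = _gmm2_log_densities(x, means, sds, weights)
        norm = logsumexp(logp, axis=0)
        ll = float(norm.sum())
        path.append(ll)
        resp = np.exp(logp - norm[None, :])
        nk = resp.sum(axis=1)
        nk = np.maximum(nk, 1e-300)
        weights = nk / n
        means = (resp @ x) / nk
        diff = x[None, :] - means[:, None]
        sds = np.sqrt((resp * diff * diff).sum(axis=1) / nk)
        low = np.flatnonzero(sds < sd_floor)
        if low.size:
            raise ComponentCollapseError(int(low[0]) + 1, float(sds[low[0]]), sd_floor)
        if np.isfinite(ll_prev) and abs(ll - ll_prev) < tol * n:
            converged = True
            break
        ll_prev = ll

    # final log-likelihood under the returned parameters
    ll = float(logsumexp(_gmm2_log_densities(x, means, sds, weights), axis=0).sum())
    path.append(ll)
    order = np.argsort(means, kind="stable")
    weights = weights / weights.sum()
    comps = [
        GaussianComponent(float(means[k]), float(sds[k]), float(weights[k])) for k in order
    ]
    return ChannelMixture(
        state1=comps[0],
        state2=comps[1],
        channel=channel,
        loglik=ll,
        n_iter=n_iter,
        converged=converged,
        loglik_path=path,
    )


# ---------------------------------------------------------------------------
# Three-component beta mixture EM (BMIQ)


def _beta_logpdf(logx, log1mx, a, b):
    return (a - 1.0) * logx + (b - 1.0) * log1mx - betaln(a, b)


def _weighted_beta_mle(s1, s2, nk, a0, b0, max_opt_iter: int = 60):
    """Maximize nk-weighted beta log-likelihood given sufficient statistics.

    s1 = sum r_i log x_i, s2 = sum r_i log(1-x_i).  Optimized over
    (log a, log b) with analytic gradient, warm-started at (a0, b0); the
    previous parameters are kept when no improvement is found, so the EM
    objective never decreases.
    """

    def negloglik(theta):
        a, b = np.exp(theta)
        psi_ab = digamma(a + b)
        val = (a - 1.0) * s1 + (b - 1.0) * s2 - nk * betaln(a, b)
        grad_a = s1 - nk * (digamma(a) - psi_ab)
        grad_b = s2 - nk * (digamma(b) - psi_ab)
        return -val, -np.array([grad_a * a, grad_b * b])

    theta0 = np.log([a0, b0])
    res = minimize(
        negloglik,
        theta0,
        jac=True,
        method="L-BFGS-B",
        bounds=[(np.log(1e-3), np.log(1e4))] * 2,
        options={"maxiter": max_opt_iter},
    )
    if np.isfinite(res.fun) and res.fun <= negloglik(theta0)[0]:
        a, b = np.exp(res.x)
        return float(a), float(b)
    return float(a0), float(b0)


def _moments_shapes(vals):
    m = float(np.mean(vals))
    v = float(np.var(vals))
    if v <= 1e-12 or not (0 < m < 1):
        return None
    common = m * (1.0 - m) / v - 1.0
    if common <= 0:
        return None
    return max(m * common, 1e-3), max((1.0 - m) * common, 1e-3)


def fit_beta_mixture3(
    betas,
    tol: float = 1e-5,
    max_iter: int = 500,
) -> BetaMixture3:
    """Fit BMIQ's three-state beta mixture by EM, deterministically.

    Initial groups are cut at beta = 0.2 and 0.8 (the canonical hypo/hyper
    boundaries of the bimodal human methylome) with method-of-moments
    shapes; a group with fewer than 10 members falls back to fixed prior
    shapes and is held fixed during the M-step.  Components are relabelled
    U/H/M by ascending mean on return.
    """
    x = np.asarray(betas, dtype=float)
    if not np.isfinite(x).all():
        raise ValidationError("beta vector contains non-finite values")
    x = np.clip(x, 1e-6, 1.0 - 1e-6)
    n = x.size
    if n < 500:
        raise DegenerateDataError(f"need >= 500 beta values, got {n}")

    groups = {"U": x[x < 0.2], "H": x[(x >= 0.2) & (x <= 0.8)], "M": x[x > 0.8]}
    shapes = np.empty((3, 2))
    frozen = np.zeros(3, dtype=bool)
    weights = np.empty(3)
    for k, label in enumerate(("U", "H", "M")):
        vals = groups[label]
        weights[k] = max(vals.size, 1) / n
        mom = _moments_shapes(vals) if vals.size >= 10 else None
        if mom is None:
            shapes[k] = PRIOR_BETA_SHAPES[label]
            frozen[k] = True
        else:
            shapes[k] = mom
    weights = weights / weights.sum()

    logx = np.log(x)
    log1mx = np.log1p(-x)
    path: list[float] = []
    ll_prev = -np.inf
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        logp = np.stack(
            [
                np.log(weights[k]) + _beta_logpdf(logx, log1mx, shapes[k, 0], shapes[k, 1])
                for k in range(3)
            ]
        )
        norm = logsumexp(logp, axis=0)
        ll = float(norm.sum())
        path.append(ll)
        resp = np.exp(logp - norm[None, :])
        nk = np.maximum(resp.sum(axis=1), 1e-300)
        weights = nk / n
        for k in range(3):
            if frozen[k]:
                continue
            s1 = float(resp[k] @ logx)
            s2 = float(resp[k] @ log1mx)
            shapes[k] = _weighted_beta_mle(s1, s2, float(nk[k]), shapes[k, 0], shapes[k, 1])
        if np.isfinite(ll_prev) and abs(ll - ll_prev) < tol * n:
            converged = True
            break
        ll_prev = ll

    logp = np.stack(
        [
            np.log(weights[k]) + _beta_logpdf(logx, log1mx, shapes[k, 0], shapes[k, 1])
            for k in range(3)
        ]
    )
    ll = float(logsumexp(logp, axis=0).sum())
    path.append(ll)

    means = shapes[:, 0] / shapes.sum(axis=1)
    order = np.argsort(means, kind="stable")
    weights = weights / weights.sum()
    comps = [
        BetaComponent(float(shapes[k, 0]), float(shapes[k, 1]), float(weights[k]))
        for k in order
    ]
    return BetaMixture3(
        U=comps[0],
        H=comps[1],
        M=comps[2],
        loglik=ll,
        n_iter=n_iter,
        converged=converged,
        loglik_path=path,
    )
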