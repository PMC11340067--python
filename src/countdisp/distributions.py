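"""Count distributions: Poisson, negative binomial (NB2), and generalized Poisson.

The generalized Poisson (GP) law of Consul and Jain is a two-parameter count
distribution that accommodates over-, under-, and equi-dispersion.  In its
natural parametrization it has parameters (alpha > 0, delta < 1) with

    P(Y = y) = alpha * (alpha + delta*y)**(y-1) / y! * exp(-alpha - delta*y)

and mean mu = alpha/(1-delta), variance alpha/(1-delta)**3.  Writing the
dispersion factor theta = 1/(1-delta), the mean parametrization used for
regression has E[Y] = mu and Var[Y] = theta**2 * mu: theta = 1 recovers the
Poisson, theta > 1 is overdispersion, theta < 1 underdispersion.  For
theta < 1 the pmf is set to zero beyond the largest integer m with
mu + m*(theta-1) > 0; the resulting truncated mass is not renormalized (see
``gp_mass_deficit``).

All pmfs are evaluated in log space with log-gamma; exponentiation happens
only at the interface.  Samplers consume a ``numpy.random.Generator`` or an
integer seed; there is no global random state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

__all__ = [
    "GPNaturalParams",
    "GPMeanParams",
    "NBParams",
    "gp_logpmf",
    "gp_convert_to_mean",
    "gp_convert_to_natural",
    "gp_moments",
    "gp_support_bound",
    "gp_mass_deficit",
    "nb_logpmf",
    "poisson_logpmf",
    "sample_counts",
    "gp_theta_lower_bound",
]

_LOG_ZERO = -np.inf


def gp_theta_lower_bound(mu: float) -> float:
    """Feasibility floor for the GP dispersion factor: max(1/2, 1 - mu/4)."""
    return max(0.5, 1.0 - mu / 4.0)


@dataclass(frozen=True)
class GPNaturalParams:
    """Natural (alpha, delta) parametrization of the generalized Poisson."""

    alpha: float
    delta: float

    def __post_init__(self) -> None:
        if not (self.alpha > 0):
            raise ValueError(f"alpha must be positive, got {self.alpha}")
        if not (self.delta < 1):
            raise ValueError(f"delta must be < 1, got {self.delta}")


@dataclass(frozen=True)
class GPMeanParams:
    """Mean/dispersion-factor (mu, theta) parametrization of the GP.

    theta = 1/(1-delta); Var = theta**2 * mu.  The feasibility constraint
    theta >= max(1/2, 1 - mu/4) is enforced on construction.
    """

    mu: float
    theta: float

    def __post_init__(self) -> None:
        if not (self.mu > 0):
            raise ValueError(f"mu must be positive, got {self.mu}")
        lo = gp_theta_lower_bound(self.mu)
        if not (self.theta >= lo):
            raise ValueError(
                f"theta={self.theta} violates feasibility theta >= {lo} at mu={self.mu}"
            )


@dataclass(frozen=True)
class NBParams:
    """NB2 parametrization: mean mu, dispersion/size alpha; Var = mu + mu**2/alpha."""

    mu: float
    alpha: float

    def __post_init__(self) -> None:
        if not (self.mu > 0):
            raise ValueError(f"mu must be positive, got {self.mu}")
        if not (self.alpha > 0):
            raise ValueError(f"alpha must be positive, got {self.alpha}")


def gp_convert_to_mean(natural: GPNaturalParams) -> GPMeanParams:
    """(alpha, delta) -> (mu, theta) via mu = alpha/(1-delta), theta = 1/(1-delta)."""
    theta = 1.0 / (1.0 - natural.delta)
    return GPMeanParams(mu=natural.alpha * theta, theta=theta)


def gp_convert_to_natural(params: GPMeanParams) -> GPNaturalParams:
    """(mu, theta) -> (alpha, delta); inverse of :func:`gp_convert_to_mean`."""
    return GPNaturalParams(alpha=params.mu / params.theta, delta=1.0 - 1.0 / params.theta)


def gp_moments(params: GPMeanParams) -> tuple[float, float]:
    """Return (mean, variance) = (mu, theta**2 * mu)."""
    return params.mu, params.theta**2 * params.mu


def gp_support_bound(params: GPMeanParams) -> int | None:
    """Largest y with positive pmf when theta < 1; ``None`` for theta >= 1.

    Solves mu + m*(theta-1) > 0 for the largest integer m.
    """
    if params.theta >= 1.0:
        return None
    # mu + m*(theta-1) > 0  <=>  m < mu/(1-theta); the inequality is strict,
    # so a boundary ratio that is an integer steps down one
    ratio = params.mu / (1.0 - params.theta)
    m = math.ceil(ratio - 1e-9) - 1  # largest integer strictly below ratio
    return max(m, 0)


def gp_logpmf(y, mu, theta):
    """Log-pmf of the generalized Poisson in the (mu, theta) parametrization.

    Vectorized over ``y``, ``mu`` and ``theta``.  Outside the support
    (negative y, or y > m when theta < 1) the result is ``-inf``.

    Parameters
    ----------
    y : int or array-like
        Non-negative integer count(s).
    mu : float or array-like
        Mean, strictly positive.
    theta : float or array-like
        Dispersion factor, must satisfy theta >= max(1/2, 1 - mu/4).
    """
    y = np.asarray(y)
    mu = np.asarray(mu, dtype=float)
    theta = np.asarray(theta, dtype=float)
    if np.any(mu <= 0):
        raise ValueError("mu must be positive")
    if np.any(theta < np.maximum(0.5, 1.0 - mu / 4.0)):
        raise ValueError("theta violates feasibility theta >= max(1/2, 1 - mu/4)")
    if np.any(y != np.floor(y)) or np.any(y < 0):
        raise ValueError("y must contain non-negative integers")

    yf = y.astype(float)
    lam = mu + (theta - 1.0) * yf  # alpha*theta + delta*theta*y, scaled
    in_support = lam > 0
    lam_safe = np.where(in_support, lam, 1.0)
    with np.errstate(divide="ignore"):
        logp = (
            np.log(mu)
            + (yf - 1.0) * np.log(lam_safe)
            - yf * np.log(theta)
            - gammaln(yf + 1.0)
            - lam_safe / theta
        )
    out = np.where(in_support, logp, _LOG_ZERO)
    if out.ndim == 0:
        return float(out)
    return out


def poisson_logpmf(y, mu):
    """Poisson log-pmf: y*ln(mu) - mu - ln(y!)."""
    y = np.asarray(y)
    mu = np.asarray(mu, dtype=float)
    if np.any(mu <= 0):
        raise ValueError("mu must be positive")
    if np.any(y != np.floor(y)) or np.any(y < 0):
        raise ValueError("y must contain non-negative integers")
    yf = y.astype(float)
    out = yf * np.log(mu) - mu - gammaln(yf + 1.0)
    if out.ndim == 0:
        return float(out)
    return out


def nb_logpmf(y, mu, alpha):
    """NB2 log-pmf with mean mu and size alpha (Var = mu + mu**2/alpha).

    log Gamma(alpha+y) - log y! - log Gamma(alpha)
      + y*log(mu/(alpha+mu)) + alpha*log(alpha/(alpha+mu))
    """
    y = np.asarray(y)
    mu = np.asarray(mu, dtype=float)
    alpha = np.asarray(alpha, dtype=float)
    if np.any(mu <= 0) or np.any(alpha <= 0):
        raise ValueError("mu and alpha must be positive")
    if np.any(y != np.floor(y)) or np.any(y < 0):
        raise ValueError("y must contain non-negative integers")
    yf = y.astype(float)
    out = (
        gammaln(alpha + yf)
        - gammaln(yf + 1.0)
        - gammaln(alpha)
        + yf * (np.log(mu) - np.log(alpha + mu))
        + alpha * (np.log(alpha) - np.log(alpha + mu))
    )
    if out.ndim == 0:
        return float(out)
    return out


def _gp_cap(mu: float, theta: float) -> int:
    """Evaluation cap for GP tail sums and inversion sampling."""
    return int(math.ceil(mu + 50.0 * theta * math.sqrt(mu) + 100.0))


def gp_mass_deficit(params: GPMeanParams) -> float:
    """Signed deviation of the total GP mass from 1.

    For theta >= 1 this is the (tiny) truncation error of summing to the
    evaluation cap; for theta < 1 it is the intrinsic non-normalization of the
    truncated pmf, which the distribution does not correct for.
    """
    bound = gp_support_bound(params)
    top = bound if bound is not None else _gp_cap(params.mu, params.theta)
    ys = np.arange(top + 1)
    total = float(np.exp(gp_logpmf(ys, params.mu, params.theta)).sum())
    return total - 1.0


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _gp_sample(mu, theta, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw GP counts by inversion of the cumulative pmf.

    ``mu`` may be a scalar (n i.i.d. draws) or a length-n array of means.
    The pmf is tabulated to cap mu + 50*theta*sqrt(mu) + 100 (or the support
    bound when theta < 1); a uniform draw beyond the tabulated cumulative
    mass raises rather than silently clipping.
    """
    mu = np.broadcast_to(np.asarray(mu, dtype=float), (n,))
    cap = max(_gp_cap(float(mu.max()), float(theta)), 1)
    bound = None
    if theta < 1.0:
        bound = gp_support_bound(GPMeanParams(float(mu.max()), float(theta)))
        cap = min(cap, bound)
    ys = np.arange(cap + 1)
    # n x (cap+1) log-pmf table; fine for the problem sizes this package targets
    logp = gp_logpmf(ys[None, :], mu[:, None], theta)
    cdf = np.cumsum(np.exp(logp), axis=1)
    total = cdf[:, -1]
    if theta >= 1.0:
        if float(total.min()) < 1.0 - 1e-8:
            raise RuntimeError("GP inversion sampler cap overflow; increase the cap")
        u = rng.random(n)
    else:
        # truncated support: draw from the (un-renormalized) law conditioned on y <= m
        u = rng.random(n) * total
    idx = (u[:, None] > cdf).sum(axis=1)
    return np.minimum(idx, cap).astype(np.int64)


def sample_counts(family: str, params, n: int, seed) -> np.ndarray:
    """Draw ``n`` i.i.d. counts from a named family.

    Parameters
    ----------
    family : {"poisson", "nb", "gp"}
    params : float | GPMeanParams | NBParams
        ``poisson`` takes a positive mean; ``nb`` an :class:`NBParams`;
        ``gp`` a :class:`GPMeanParams`.
    n : int
        Number of draws, >= 1.
    seed : int or numpy.random.Generator
        Identical integer seeds give identical sequences (PCG64).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = _as_rng(seed)
    if family == "poisson":
        mu = float(params)
        if mu <= 0:
            raise ValueError("poisson mean must be positive")
        return rng.poisson(mu, size=n).astype(np.int64)
    if family == "nb":
        if not isinstance(params, NBParams):
            params = NBParams(*params)
        # numpy's (n, p) parametrization: size alpha, p = alpha/(alpha+mu)
        p = params.alpha / (params.alpha + params.mu)
        return rng.negative_binomial(params.alpha, p, size=n).astype(np.int64)
    if family == "gp":
        if not isinstance(params, GPMeanParams):
            params = GPMeanParams(*params)
        return _gp_sample(params.mu, params.theta, n, rng)
    raise ValueError(f"unknown family {family!r}")


def sample_gp_counts(mu, theta: float, rng: np.random.Generator) -> np.ndarray:
    """Draw one GP count per element of ``mu`` (heterogeneous means, shared theta)."""
    mu = np.asarray(mu, dtype=float)
    return _gp_sample(mu, theta, mu.shape[0], rng)
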