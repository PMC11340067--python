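"""Design-matrix construction and maximum-likelihood count regression.

Fits log-link Poisson, NB2, and generalized Poisson (GP) regressions

    ln mu_i = x_i' beta

by direct maximization of the family log-likelihood.  The NB2 dispersion
``alpha`` and the GP dispersion factor ``theta`` are estimated on the log
scale as one extra free parameter each (an intercept of the dispersion
equation), giving positivity without constrained optimization.  Standard
errors come from the inverse observed information (numerical Hessian of the
analytic score); Wald z and two-sided normal p-values accompany each
coefficient.

The council data schema has five continuous covariates (PPLHIV %, population,
GDP, number of health facilities, % male among cases), a rural/urban factor
(reference Rural) and a 7-level zone factor (reference Northern).  The full
specification yields a 13-column design; population and GDP are
log-transformed by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import digamma
from scipy.stats import norm

from .distributions import gp_logpmf, nb_logpmf, poisson_logpmf

__all__ = [
    "RESIDENCE_LEVELS",
    "ZONE_LEVELS",
    "ModelSpec",
    "DesignMatrix",
    "FitResult",
    "build_design",
    "negloglik",
    "fit_model",
    "wald_inference",
    "predict_mean",
]

RESIDENCE_LEVELS = ("Rural", "Urban")
ZONE_LEVELS = (
    "Lake",
    "Southern",
    "Southern Highlands",
    "Central",
    "Eastern",
    "Northern",
    "Western",
)
# dummy order as reported in the field's coefficient tables (reference Northern)
_ZONE_DUMMY_ORDER = ("Central", "Eastern", "Lake", "Southern", "Southern Highlands", "Western")

_CONTINUOUS = ("pplhiv_pct", "population", "gdp", "n_facilities", "pct_male")

FAMILIES = ("poisson", "nb", "gp")


@dataclass
class ModelSpec:
    """What to regress and how.

    Parameters
    ----------
    response : {"count_5_59", "count_60plus", "total"}
        Which count is modelled; ``"total"`` sums the two age groups.
    transforms : dict
        Per-covariate transform, one of ``"identity"``, ``"log"``,
        ``"standardize"``.  Default log-transforms population and GDP and
        leaves percentages and facility counts raw.
    covariates : tuple
        Ordered continuous covariates entering the design.
    reference_residence, reference_zone : str
        Reference levels for the two factors.
    """

    response: str = "total"
    transforms: dict = field(
        default_factory=lambda: {"population": "log", "gdp": "log"}
    )
    covariates: tuple = _CONTINUOUS
    reference_residence: str = "Rural"
    reference_zone: str = "Northern"
    family: str | None = None

    def __post_init__(self) -> None:
        if self.response not in ("count_5_59", "count_60plus", "total"):
            raise ValueError(f"unknown response {self.response!r}")
        if self.reference_residence not in RESIDENCE_LEVELS:
            raise ValueError(f"unknown residence level {self.reference_residence!r}")
        if self.reference_zone not in ZONE_LEVELS:
            raise ValueError(f"unknown zone level {self.reference_zone!r}")
        for cov, tr in self.transforms.items():
            if tr not in ("identity", "log", "standardize"):
                raise ValueError(f"unknown transform {tr!r} for {cov!r}")


@dataclass
class DesignMatrix:
    """A complete-case numeric design with a deterministic column order."""

    values: np.ndarray
    column_names: list
    n_used: int
    dropped_rows: list
    response: np.ndarray | None = None

    @property
    def k(self) -> int:
        return self.values.shape[1]


def _response_series(df: pd.DataFrame, response: str) -> pd.Series:
    if response == "total":
        return df["count_5_59"] + df["count_60plus"]
    return df[response]


def build_design(records: pd.DataFrame, spec: ModelSpec) -> DesignMatrix:
    """Build the n x 13 design matrix and response vector from council records.

    Dummy-codes residence (reference Rural) and zone (reference Northern),
    applies the per-covariate transforms, and drops rows with any missing
    required field (complete-case), reporting them in ``dropped_rows``.
    """
    if len(records) == 0:
        raise ValueError("no records supplied")
    df = records.reset_index(drop=True)

    required = list(spec.covariates) + ["residence", "zone"]
    resp_cols = (
        ["count_5_59", "count_60plus"] if spec.response == "total" else [spec.response]
    )
    bad_res = set(df["residence"].dropna()) - set(RESIDENCE_LEVELS)
    if bad_res:
        raise ValueError(f"unknown residence level(s): {sorted(bad_res)}")
    bad_zone = set(df["zone"].dropna()) - set(ZONE_LEVELS)
    if bad_zone:
        raise ValueError(f"unknown zone level(s): {sorted(bad_zone)}")

    complete = df[required + resp_cols].notna().all(axis=1)
    dropped = df.index[~complete].tolist()
    if "council_id" in df.columns:
        dropped = df.loc[~complete, "council_id"].tolist()
    kept = df[complete]
    if len(kept) == 0:
        raise ValueError("all rows dropped by complete-case filtering")

    cols: list[np.ndarray] = [np.ones(len(kept))]
    names: list[str] = ["(Intercept)"]
    for cov in spec.covariates:
        x = kept[cov].to_numpy(dtype=float)
        tr = spec.transforms.get(cov, "identity")
        if tr == "log":
            if np.any(x <= 0):
                raise ValueError(f"log transform of {cov!r} requires positive values")
            x = np.log(x)
            names.append(f"log({cov})")
        elif tr == "standardize":
            x = (x - x.mean()) / x.std(ddof=0)
            names.append(f"z({cov})")
        else:
            names.append(cov)
        cols.append(x)

    for lev in RESIDENCE_LEVELS:
        if lev != spec.reference_residence:
            cols.append((kept["residence"] == lev).to_numpy(dtype=float))
            names.append(lev)
    for lev in _ZONE_DUMMY_ORDER if spec.reference_zone == "Northern" else [
        z for z in ZONE_LEVELS if z != spec.reference_zone
    ]:
        cols.append((kept["zone"] == lev).to_numpy(dtype=float))
        names.append(lev)

    y = _response_series(kept, spec.response).to_numpy(dtype=float)
    if np.any(y < 0) or np.any(y != np.floor(y)):
        raise ValueError("response must contain non-negative integers")

    return DesignMatrix(
        values=np.column_stack(cols),
        column_names=names,
        n_used=len(kept),
        dropped_rows=dropped,
        response=y,
    )


@dataclass
class FitResult:
    """A maximum-likelihood fit of one family."""

    family: str
    coefficients: np.ndarray  # beta, plus log-dispersion for nb/gp
    names: list
    std_errors: np.ndarray
    z_values: np.ndarray
    p_values: np.ndarray
    loglik: float
    vcov: np.ndarray
    converged: bool
    n_used: int
    k_params: int
    grad_norm: float

    @property
    def beta(self) -> np.ndarray:
        """Regression coefficients (excluding the dispersion parameter)."""
        return self.coefficients[: self._n_beta]

    @property
    def _n_beta(self) -> int:
        return self.k_params - (0 if self.family == "poisson" else 1)

    @property
    def dispersion(self) -> float | None:
        """theta-hat for gp, alpha-hat for nb, None for poisson."""
        if self.family == "poisson":
            return None
        return float(np.exp(self.coefficients[-1]))

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "estimate": self.coefficients,
                "std_error": self.std_errors,
                "z_value": self.z_values,
                "p_value": self.p_values,
            },
            index=self.names,
        )


_ETA_MAX = 50.0  # linear predictors beyond this are rejected, not clipped
_PENALTY = 1e10


def _unpack(family: str, params: np.ndarray, k: int):
    beta = params[:k]
    disp = None if family == "poisson" else float(np.exp(params[k]))
    return beta, disp


def negloglik(family: str, beta, disp, X: np.ndarray, y: np.ndarray) -> float:
    """Total negative log-likelihood of a family at (beta, dispersion).

    ``disp`` is theta for gp, alpha for nb, ignored for poisson.  Infeasible
    GP points (theta below the per-observation floor max(1/2, 1 - mu/4), or a
    non-finite linear predictor) return ``inf``.
    """
    beta = np.asarray(beta, dtype=float)
    eta = X @ beta
    if not np.all(np.isfinite(eta)) or np.max(np.abs(eta)) > _ETA_MAX:
        return np.inf
    mu = np.exp(eta)
    if family == "poisson":
        return float(-poisson_logpmf(y, mu).sum())
    if family == "nb":
        if disp is None or disp <= 0:
            return np.inf
        return float(-nb_logpmf(y, mu, disp).sum())
    if family == "gp":
        if disp is None or disp < float(np.max(np.maximum(0.5, 1.0 - mu / 4.0))):
            return np.inf
        lam = mu + (disp - 1.0) * y
        if np.any(lam <= 0):
            return np.inf
        return float(-gp_logpmf(y, mu, disp).sum())
    raise ValueError(f"unknown family {family!r}")


def _mean_obj_and_grad(family: str, params: np.ndarray, X: np.ndarray, y: np.ndarray):
    """(negloglik/n, gradient/n) with analytic scores; penalty outside feasibility."""
    n, k = X.shape
    beta = params[:k]
    eta = X @ beta
    if not np.all(np.isfinite(eta)) or np.max(np.abs(eta)) > _ETA_MAX:
        return _PENALTY, np.zeros_like(params)
    mu = np.exp(eta)

    if family == "poisson":
        nll = -float(poisson_logpmf(y, mu).sum())
        grad = X.T @ (mu - y)
        return nll / n, grad / n

    if family == "nb":
        alpha = float(np.exp(params[k]))
        nll = -float(nb_logpmf(y, mu, alpha).sum())
        dl_dmu = y / mu - (y + alpha) / (alpha + mu)
        gbeta = -X.T @ (dl_dmu * mu)
        dl_dalpha = (
            digamma(alpha + y)
            - digamma(alpha)
            + np.log(alpha / (alpha + mu))
            + 1.0
            - (y + alpha) / (alpha + mu)
        )
        gdisp = -float(dl_dalpha.sum()) * alpha  # chain rule through log alpha
        return nll / n, np.append(gbeta, gdisp) / n

    if family == "gp":
        theta = float(np.exp(params[k]))
        lo = float(np.max(np.maximum(0.5, 1.0 - mu / 4.0)))
        lam = mu + (theta - 1.0) * y
        if theta < lo or np.any(lam <= 0):
            return _PENALTY, np.zeros_like(params)
        nll = -float(gp_logpmf(y, mu, theta).sum())
        dl_dmu = 1.0 / mu + (y - 1.0) / lam - 1.0 / theta
        gbeta = -X.T @ (dl_dmu * mu)
        dl_dtheta = y * (y - 1.0) / lam - y / theta - (y - mu) / theta**2
        gdisp = -float(dl_dtheta.sum()) * theta
        return nll / n, np.append(gbeta, gdisp) / n

    raise ValueError(f"unknown family {family!r}")


def _numerical_hessian(fun, x: np.ndarray, h: float = 1e-5) -> np.ndarray:
    """Central-difference Hessian of a scalar function via its gradient."""
    p = x.size
    H = np.zeros((p, p))
    for j in range(p):
        step = h * max(1.0, abs(x[j]))
        xp, xm = x.copy(), x.copy()
        xp[j] += step
        xm[j] -= step
        _, gp_ = fun(xp)
        _, gm_ = fun(xm)
        H[:, j] = (gp_ - gm_) / (2.0 * step)
    return 0.5 * (H + H.T)


_GTOL = 1e-6  # max-norm of the mean-negloglik gradient


def fit_model(
    family: str,
    X: DesignMatrix | np.ndarray,
    y: np.ndarray | None = None,
    start: np.ndarray | None = None,
    column_names: list | None = None,
) -> FitResult:
    """Maximum-likelihood fit of one family on a design.

    NB and GP fits start from the Poisson solution with the dispersion at its
    moment estimate.  Convergence requires the max-norm of the
    per-observation score to fall below 1e-6; the flag is honest — a fit that
    fails the criterion is returned flagged, never silently wrong.
    """
    if isinstance(X, DesignMatrix):
        names = list(X.column_names)
        if y is None:
            y = X.response
        X = X.values
    else:
        X = np.asarray(X, dtype=float)
        names = list(column_names) if column_names else [f"x{j}" for j in range(X.shape[1])]
    y = np.asarray(y, dtype=float)
    n, k = X.shape
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}")
    k_params = k + (0 if family == "poisson" else 1)
    if n <= k_params:
        raise ValueError(f"n_used={n} must exceed k_params={k_params}")
    if np.any(y < 0) or np.any(y != np.floor(y)):
        raise ValueError("y must contain non-negative integers")
    if np.linalg.matrix_rank(X) < k:
        raise np.linalg.LinAlgError("design matrix is rank deficient (singular information)")

    if family == "poisson":
        x0 = start if start is not None else _poisson_start(X, y)
    else:
        beta0 = start[:k] if start is not None else fit_model("poisson", X, y).beta
        mu0 = np.exp(np.clip(X @ beta0, -_ETA_MAX, _ETA_MAX))
        ratio = float(np.sum((y - mu0) ** 2 / mu0) / max(n - k, 1))
        if family == "gp":
            disp0 = np.log(max(np.sqrt(max(ratio, 1.0)), 1.0))
        else:
            excess = max(ratio - 1.0, 1e-2)
            disp0 = np.log(max(float(mu0.mean()) / excess, 1e-3))
        x0 = np.append(beta0, disp0)

    res = optimize.minimize(
        lambda p: _mean_obj_and_grad(family, p, X, y),
        x0,
        jac=True,
        method="BFGS",
        options={"gtol": _GTOL / 10.0, "maxiter": 500},
    )
    xhat = res.x
    # polish with Newton steps off the numerical Hessian if BFGS stalled short
    _, g = _mean_obj_and_grad(family, xhat, X, y)
    gnorm = float(np.max(np.abs(g)))
    if gnorm > _GTOL:
        for _ in range(10):
            H = _numerical_hessian(lambda p: _mean_obj_and_grad(family, p, X, y), xhat)
            try:
                step = np.linalg.solve(H, g)
            except np.linalg.LinAlgError:
                break
            cand = xhat - step
            fc, gc = _mean_obj_and_grad(family, cand, X, y)
            if not np.isfinite(fc) or fc >= _PENALTY:
                break
            xhat, g = cand, gc
            gnorm = float(np.max(np.abs(g)))
            if gnorm <= _GTOL:
                break
    converged = gnorm <= _GTOL

    H = _numerical_hessian(lambda p: _mean_obj_and_grad(family, p, X, y), xhat) * n
    try:
        vcov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        vcov = np.linalg.pinv(H)
        converged = False
    diag = np.diag(vcov).copy()
    if np.any(diag <= 0):
        converged = False
        diag = np.where(diag > 0, diag, np.nan)
    se = np.sqrt(diag)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = xhat / se
    p = 2.0 * norm.sf(np.abs(z))

    if family != "poisson":
        names = names + [("log(theta)" if family == "gp" else "log(alpha)")]
    ll = -negloglik(
        family, xhat[:k], None if family == "poisson" else float(np.exp(xhat[k])), X, y
    )
    return FitResult(
        family=family,
        coefficients=xhat,
        names=names,
        std_errors=se,
        z_values=z,
        p_values=p,
        loglik=ll,
        vcov=vcov,
        converged=bool(converged),
        n_used=n,
        k_params=k_params,
        grad_norm=gnorm,
    )


def _poisson_start(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Cheap start: intercept at ln(mean), slopes at 0."""
    x0 = np.zeros(X.shape[1])
    ybar = max(float(y.mean()), 1e-8)
    # assumes the first all-ones column is the intercept; otherwise zeros are fine
    ones = np.where(np.all(X == 1.0, axis=0))[0]
    if ones.size:
        x0[ones[0]] = np.log(ybar)
    return x0


def wald_inference(fit: FitResult) -> pd.DataFrame:
    """Coefficient table: estimate, SE, z = estimate/SE, two-sided normal p."""
    if np.any(fit.std_errors == 0):
        raise ZeroDivisionError("zero standard error; z undefined")
    return fit.summary()


def predict_mean(fit: FitResult, X: DesignMatrix | np.ndarray) -> np.ndarray:
    """Predicted means mu-hat = exp(x' beta-hat); strictly positive."""
    if isinstance(X, DesignMatrix):
        if list(X.column_names) != list(fit.names[: len(X.column_names)]):
            raise ValueError("design columns do not match the fitted model")
        X = X.values
    X = np.asarray(X, dtype=float)
    if X.shape[1] != fit.beta.size:
        raise ValueError(
            f"design has {X.shape[1]} columns, fit expects {fit.beta.size}"
        )
    return np.exp(X @ fit.beta)
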