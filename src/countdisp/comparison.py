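"""Model adequacy: information criteria, Pearson chi-square dispersion, ranking.

For a fitted family with maximized log-likelihood l, k estimated parameters
(dispersion parameters counted) and effective sample size n:

    AIC  = -2 l + 2 k
    AICc = AIC + 2 k (k + 1) / (n - k - 1)
    BIC  = -2 l + k ln n

The Pearson chi-square statistic sums squared Pearson residuals with the
family's own variance function (Poisson: mu; NB2: mu + mu**2/alpha;
GP: theta**2 mu) over df = n - k.  A ratio chi2/df well above one flags
overdispersion the model has not absorbed; close to one means dispersion is
adequately modelled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .regression import DesignMatrix, FitResult, predict_mean

__all__ = ["ComparisonRow", "information_criteria", "pearson_chi2", "comparison_table"]

COMPARISON_COLUMNS = [
    "model",
    "loglik",
    "minus2loglik",
    "aic",
    "aicc",
    "bic",
    "pearson_chi2",
    "df",
    "pearson_ratio",
    "n_used",
    "k_params",
]


@dataclass
class ComparisonRow:
    model: str
    loglik: float
    minus2loglik: float
    aic: float
    aicc: float
    bic: float
    pearson_chi2: float
    df: int
    pearson_ratio: float
    n_used: int
    k_params: int


def information_criteria(loglik: float, k: int, n: int) -> tuple[float, float, float]:
    """Return (AIC, AICc, BIC); ``n`` is passed explicitly so published
    tables can be reproduced at their stated effective sample size."""
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n} <= k+1={k + 1}")
    aic = -2.0 * loglik + 2.0 * k
    aicc = aic + 2.0 * k * (k + 1.0) / (n - k - 1.0)
    bic = -2.0 * loglik + k * np.log(n)
    return aic, aicc, bic


def _variance(fit: FitResult, mu: np.ndarray) -> np.ndarray:
    if fit.family == "poisson":
        return mu
    if fit.family == "nb":
        return mu + mu**2 / fit.dispersion
    if fit.family == "gp":
        return fit.dispersion**2 * mu
    raise ValueError(f"unknown family {fit.family!r}")


def pearson_chi2(
    fit: FitResult, X: DesignMatrix | np.ndarray, y: np.ndarray | None = None
) -> tuple[float, int, float]:
    """Pearson chi-square, residual df = n - k_params, and their ratio."""
    if isinstance(X, DesignMatrix) and y is None:
        y = X.response
    y = np.asarray(y, dtype=float)
    mu = predict_mean(fit, X)
    df = fit.n_used - fit.k_params
    if df <= 0:
        raise ValueError(f"non-positive residual df: {df}")
    chi2 = float(np.sum((y - mu) ** 2 / _variance(fit, mu)))
    return chi2, df, chi2 / df


def comparison_table(
    fits,
    X: DesignMatrix | np.ndarray | None = None,
    y: np.ndarray | None = None,
    n: int | None = None,
) -> pd.DataFrame:
    """One adequacy row per fitted model, ranked ascending by AIC.

    Ties break by BIC, then model name.  When the design and response are
    supplied the Pearson columns are computed; otherwise they are NaN.
    """
    fits = list(fits)
    if not fits:
        raise ValueError("no fits supplied")
    rows = []
    for fit in fits:
        n_eff = n if n is not None else fit.n_used
        aic, aicc, bic = information_criteria(fit.loglik, fit.k_params, n_eff)
        if X is not None:
            chi2, df, ratio = pearson_chi2(fit, X, y)
        else:
            chi2, df, ratio = np.nan, n_eff - fit.k_params, np.nan
        rows.append(
            ComparisonRow(
                model=fit.family,
                loglik=fit.loglik,
                minus2loglik=-2.0 * fit.loglik,
                aic=aic,
                aicc=aicc,
                bic=bic,
                pearson_chi2=chi2,
                df=df,
                pearson_ratio=ratio,
                n_used=n_eff,
                k_params=fit.k_params,
            )
        )
    table = pd.DataFrame([vars(r) for r in rows], columns=COMPARISON_COLUMNS)
    return (
        table.sort_values(["aic", "bic", "model"], kind="mergesort")
        .reset_index(drop=True)
    )
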