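"""Synthetic council-level datasets with the structure the analysis assumes.

The study data (184 Tanzanian mainland councils, 2020, DHIS2/NBS) are not
public, so this module generates datasets that emulate their statistical
shape: a 7-level zone factor and a rural/urban factor with frequencies
matching the published margins, right-skewed continuous covariates, and
counts drawn from a generalized Poisson law with log-link mean exp(x'beta)
and dispersion factor theta > 1.  The default coefficient vector is the
study's published GP estimate, so synthetic data echo the reported effect
pattern (urban excess, northern-zone reference advantage, negative GDP
effect).

Each council's total count is split into two age-group counts (5-59 and
60+).  Because the GP family is closed under convolution at equal theta, the
two parts are drawn as GP(share*mu, theta) and GP((1-share)*mu, theta), so
the total remains exactly GP(mu, theta) and the generator truth is exact for
the default "total" response.

Covariates are drawn on their raw scale (population, GDP as positive
log-normals) and the regression truth applies to the transformed (log)
scale, exercising the same transform pipeline a user CSV goes through.
Sampling uses numpy's PCG64 Generator; one integer seed fully determines the
output.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .distributions import GPMeanParams, NBParams, sample_counts, sample_gp_counts
from .regression import ZONE_LEVELS, ModelSpec, build_design

__all__ = ["SyntheticConfig", "default_config", "generate", "truth_report"]

# zone frequencies from the published 184-council margins
_ZONE_COUNTS = {
    "Central": 15,
    "Eastern": 24,
    "Lake": 36,
    "Northern": 31,
    "Southern": 23,
    "Southern Highlands": 32,
    "Western": 23,
}

# published GP coefficient vector on the design scale, in design-column order:
# intercept, PPLHIV %, log(population), log(GDP), facilities, % male,
# Urban, Central, Eastern, Lake, Southern, Southern Highlands, Western
_BETA_TRUE = {
    "(Intercept)": 3.5400,
    "pplhiv_pct": 0.0616,
    "log(population)": 0.2264,
    "log(gdp)": -0.1507,
    "n_facilities": 0.0132,
    "pct_male": -0.0017,
    "Urban": 1.1720,
    "Central": -0.8480,
    "Eastern": -0.6483,
    "Lake": -0.7265,
    "Southern": -0.8064,
    "Southern Highlands": -0.7467,
    "Western": -0.3392,
}

# continuous covariate laws, chosen so the induced count distribution is
# study-like: majority of councils below 50, maxima around a thousand,
# strong right skew (see docs/methods.md)
_DEFAULT_COVARIATE_LAWS = {
    "pplhiv_pct": {"law": "gamma", "shape": 2.0, "scale": 2.5},
    "population": {"law": "lognormal", "mean_log": 12.0, "sd_log": 0.8},
    "gdp": {"law": "lognormal", "mean_log": 19.5, "sd_log": 0.9},
    "n_facilities": {"law": "gamma_int", "shape": 2.0, "scale": 25.0},
    "pct_male": {"law": "normal_clipped", "mean": 47.0, "sd": 8.0, "lo": 0.0, "hi": 100.0},
}


@dataclass
class SyntheticConfig:
    """Generator truth: who the councils are and how their counts arise."""

    n_councils: int = 184
    zone_probs: dict = field(
        default_factory=lambda: {z: c / 184 for z, c in _ZONE_COUNTS.items()}
    )
    urban_prob: float = 45 / 184
    covariate_laws: dict = field(default_factory=lambda: dict(_DEFAULT_COVARIATE_LAWS))
    beta_true: dict = field(default_factory=lambda: dict(_BETA_TRUE))
    family: str = "gp"
    dispersion_true: float = 2.0  # theta for gp, alpha for nb
    share_5_59: float = 0.6  # fraction of a council's mean in the 5-59 group
    missing_rate: float = 7 / 184
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_councils < 1:
            raise ValueError("n_councils must be >= 1")
        if abs(sum(self.zone_probs.values()) - 1.0) > 1e-9:
            raise ValueError("zone_probs must sum to 1")
        if not set(self.zone_probs) <= set(ZONE_LEVELS):
            raise ValueError("zone_probs keys must be study zone levels")
        if not (0.0 <= self.urban_prob <= 1.0 and 0.0 <= self.missing_rate <= 1.0):
            raise ValueError("probabilities must lie in [0, 1]")
        if not (0.0 < self.share_5_59 < 1.0):
            raise ValueError("share_5_59 must lie in (0, 1)")
        if self.family not in ("poisson", "nb", "gp"):
            raise ValueError(f"unknown family {self.family!r}")
        if self.family != "poisson" and self.dispersion_true <= 0:
            raise ValueError("dispersion must be positive")
        if self.family == "gp" and self.dispersion_true < 0.5:
            raise ValueError("gp dispersion factor theta must be >= 1/2")


def default_config(seed: int = 0) -> SyntheticConfig:
    """The study-shaped default: 184 councils, published margins and betas."""
    return SyntheticConfig(seed=seed)


def _draw_covariate(law: dict, n: int, rng: np.random.Generator) -> np.ndarray:
    kind = law["law"]
    if kind == "gamma":
        return rng.gamma(law["shape"], law["scale"], size=n)
    if kind == "gamma_int":  # right-skewed counts, e.g. health facilities
        return np.round(rng.gamma(law["shape"], law["scale"], size=n))
    if kind == "lognormal":
        return np.exp(rng.normal(law["mean_log"], law["sd_log"], size=n))
    if kind == "poisson":
        return rng.poisson(law["lam"], size=n).astype(float)
    if kind == "normal_clipped":
        return np.clip(rng.normal(law["mean"], law["sd"], size=n), law["lo"], law["hi"])
    raise ValueError(f"unknown covariate law {kind!r}")


def generate(config: SyntheticConfig) -> tuple[pd.DataFrame, dict]:
    """Draw a council dataset; returns (records, truth).

    ``records`` follows the pipeline CSV schema (council_id, zone, residence,
    pplhiv_pct, population, gdp, n_facilities, pct_male, count_5_59,
    count_60plus).  ``truth`` is the :func:`truth_report` of the config with
    the realized per-council means attached.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_councils

    zones = rng.choice(
        list(config.zone_probs), p=list(config.zone_probs.values()), size=n
    )
    residence = np.where(rng.random(n) < config.urban_prob, "Urban", "Rural")
    df = pd.DataFrame(
        {
            "council_id": [f"C{i:03d}" for i in range(n)],
            "zone": zones,
            "residence": residence,
        }
    )
    for cov, law in config.covariate_laws.items():
        df[cov] = _draw_covariate(law, n, rng)

    # the truth applies on the transformed design scale (log pop, log GDP)
    df["count_5_59"] = 0
    df["count_60plus"] = 0
    design = build_design(df, ModelSpec(response="total"))
    beta = np.array([config.beta_true[name] for name in design.column_names])
    mu = np.exp(design.values @ beta)

    disp = config.dispersion_true
    s = config.share_5_59
    if config.family == "gp":
        GPMeanParams(float(mu.min() * min(s, 1 - s)), disp)  # feasibility check
        y1 = sample_gp_counts(s * mu, disp, rng)
        y2 = sample_gp_counts((1.0 - s) * mu, disp, rng)
    elif config.family == "poisson":
        y1 = rng.poisson(s * mu)
        y2 = rng.poisson((1.0 - s) * mu)
    else:  # nb: thin each council's NB total binomially by age share
        total = np.array(
            [sample_counts("nb", NBParams(m, disp), 1, rng)[0] for m in mu]
        )
        y1 = rng.binomial(total, s)
        y2 = total - y1

    df["count_5_59"] = pd.array(y1, dtype="Int64")
    df["count_60plus"] = pd.array(y2, dtype="Int64")
    missing = rng.random(n) < config.missing_rate
    df.loc[missing, ["count_5_59", "count_60plus"]] = pd.NA

    truth = truth_report(config)
    truth["mu_mean"] = float(mu.mean())
    truth["n_missing"] = int(missing.sum())
    return df, truth


def truth_report(config: SyntheticConfig) -> dict:
    """The recovery-test target: true betas, family, dispersion, transforms."""
    return {
        "beta_true": dict(config.beta_true),
        "family": config.family,
        "dispersion_true": config.dispersion_true,
        "transforms": {"population": "log", "gdp": "log"},
        "n_councils": config.n_councils,
        "seed": config.seed,
    }


def config_to_dict(config: SyntheticConfig) -> dict:
    return dataclasses.asdict(config)


def config_from_dict(d: dict) -> SyntheticConfig:
    return SyntheticConfig(**d)


def save_config(config: SyntheticConfig, path) -> None:
    with open(path, "w") as fh:
        json.dump(config_to_dict(config), fh, indent=2)


def load_config(path) -> SyntheticConfig:
    with open(path) as fh:
        return config_from_dict(json.load(fh))
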