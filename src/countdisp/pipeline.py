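"""End-to-end orchestration: descriptives, three-family fits, comparison, report.

``run_analysis`` mirrors the study's results flow: dispersion summaries per
age group, factor-by-category contingency tables with chi-square tests, one
maximum-likelihood fit per requested family, and the ranked adequacy table.
The report serializes to schema-versioned JSON (``countdisp-report/1``) or a
CSV bundle with one file per table; numbers are written at full precision.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import __version__
from .comparison import comparison_table
from .descriptive import (
    ChiSquareResult,
    ContingencyTable,
    chi2_independence,
    contingency_table,
    dispersion_summary,
)
from .regression import FitResult, ModelSpec, build_design, fit_model

__all__ = ["AnalysisReport", "run_analysis", "write_report", "read_report"]

logger = logging.getLogger("countdisp")

REPORT_SCHEMA = "countdisp-report/1"

_AGE_COLUMNS = {"5_59": "count_5_59", "60plus": "count_60plus"}


@dataclass
class AnalysisReport:
    """Everything one analysis run produced, with provenance to re-run it."""

    data_summary: dict
    descriptive_tables: dict
    fits: dict  # family -> FitResult
    fit_errors: dict  # family -> message, for gracefully degraded fits
    comparison: pd.DataFrame
    provenance: dict

    def to_dict(self) -> dict:
        out = {
            "schema": REPORT_SCHEMA,
            "data_summary": self.data_summary,
            "descriptive_tables": {
                key: _descriptive_to_dict(tab, test)
                for key, (tab, test) in self.descriptive_tables.items()
            },
            "fits": {fam: _fit_to_dict(fit) for fam, fit in self.fits.items()},
            "fit_errors": dict(self.fit_errors),
            "comparison": self.comparison.to_dict(orient="records"),
            "provenance": self.provenance,
        }
        return out


def _fit_to_dict(fit: FitResult) -> dict:
    return {
        "family": fit.family,
        "names": list(fit.names),
        "coefficients": fit.coefficients.tolist(),
        "std_errors": fit.std_errors.tolist(),
        "z_values": fit.z_values.tolist(),
        "p_values": fit.p_values.tolist(),
        "dispersion": fit.dispersion,
        "loglik": fit.loglik,
        "converged": fit.converged,
        "n_used": fit.n_used,
        "k_params": fit.k_params,
    }


def _descriptive_to_dict(tab: ContingencyTable, test: ChiSquareResult | None) -> dict:
    out = {
        "row_factor": tab.row_factor,
        "row_levels": list(tab.row_levels),
        "col_categories": list(tab.col_categories),
        "counts": tab.counts.tolist(),
        "percentages": tab.percentages.tolist(),
        "total": tab.total,
        "chi2": None,
        "df": None,
        "p_value": None,
        "small_expected_warning": None,
    }
    if test is not None:
        out.update(
            chi2=test.statistic,
            df=test.df,
            p_value=test.p_value,
            small_expected_warning=test.small_expected_warning,
        )
    return out


def run_analysis(
    records: pd.DataFrame,
    spec: ModelSpec | None = None,
    families=("poisson", "nb", "gp"),
    min_records: int = 30,
    provenance: dict | None = None,
) -> AnalysisReport:
    """Descriptive stage, per-family ML fits, and the ranked comparison.

    A family whose fit raises is flagged in ``fit_errors`` and the rest of
    the report still completes; only all families failing is an error.
    """
    spec = spec or ModelSpec()
    design = build_design(records, spec)
    if design.n_used < min_records:
        raise ValueError(
            f"only {design.n_used} complete records; need at least {min_records}"
        )
    logger.info(
        "rows read: %d; complete-case rows: %d; dropped: %d",
        len(records),
        design.n_used,
        len(design.dropped_rows),
    )

    data_summary = {}
    for label, col in _AGE_COLUMNS.items():
        counts = records[col].dropna().to_numpy(dtype=float)
        if counts.size >= 2:
            s = dispersion_summary(counts)
            data_summary[label] = {
                "mean": s.mean,
                "variance": s.variance,
                "ratio": s.ratio,
                "skewness": s.skewness,
                "histogram_bins": s.histogram_bins.tolist(),
                "bin_edges": s.bin_edges.tolist(),
            }

    descriptive_tables = {}
    for label, col in _AGE_COLUMNS.items():
        for factor in ("residence", "zone"):
            tab = contingency_table(records, factor, col)
            try:
                test = chi2_independence(tab)
            except ValueError as exc:  # e.g. an empty count category in this sample
                logger.warning("chi-square skipped for %s/%s: %s", factor, label, exc)
                test = None
            descriptive_tables[f"{factor}_{label}"] = (tab, test)

    fits: dict[str, FitResult] = {}
    fit_errors: dict[str, str] = {}
    for family in families:
        try:
            fit = fit_model(family, design)
            fits[family] = fit
            logger.info("%s fit: converged=%s loglik=%.3f", family, fit.converged, fit.loglik)
        except Exception as exc:  # degrade gracefully, report the rest
            fit_errors[family] = f"{type(exc).__name__}: {exc}"
            logger.warning("%s fit failed: %s", family, exc)
    if not fits:
        raise RuntimeError(f"all fits failed: {fit_errors}")

    comp = comparison_table(fits.values(), design)

    prov = dict(provenance or {})
    prov.update(
        {
            "software_version": __version__,
            "response": spec.response,
            "transforms": dict(spec.transforms),
            "families": list(families),
            "n_records": int(len(records)),
            "n_used": design.n_used,
            "dropped_rows": list(design.dropped_rows),
        }
    )
    return AnalysisReport(
        data_summary=data_summary,
        descriptive_tables=descriptive_tables,
        fits=fits,
        fit_errors=fit_errors,
        comparison=comp,
        provenance=prov,
    )


def write_report(report: AnalysisReport, path, format: str = "json") -> None:
    """Serialize a report to JSON or to a CSV bundle (one file per table)."""
    path = Path(path)
    if format == "json":
        with open(path, "w") as fh:
            json.dump(report.to_dict(), fh, indent=2)
        return
    if format == "csv-bundle":
        path.mkdir(parents=True, exist_ok=True)
        for key, (tab, test) in report.descriptive_tables.items():
            out = tab.to_dataframe()
            out["p_value"] = test.p_value if test is not None else float("nan")
            out.to_csv(path / f"descriptive_{key}.csv", index_label=tab.row_factor)
        for fam, fit in report.fits.items():
            fit.summary().to_csv(path / f"coefficients_{fam}.csv", index_label="term")
        comp = report.comparison.rename(columns={"loglik": "logLik", "pearson_ratio": "ratio"})
        comp[["model", "logLik", "aic", "bic", "aicc", "pearson_chi2", "df", "ratio"]].rename(
            columns={"aic": "AIC", "bic": "BIC", "aicc": "AICc"}
        ).to_csv(path / "comparison.csv", index=False)
        with open(path / "provenance.json", "w") as fh:
            json.dump(
                {"schema": REPORT_SCHEMA, "provenance": report.provenance,
                 "fit_errors": report.fit_errors},
                fh,
                indent=2,
            )
        return
    raise ValueError(f"unknown report format {format!r}")


def read_report(path) -> dict:
    """Load a JSON report back as a plain dict (schema-checked)."""
    with open(path) as fh:
        d = json.load(fh)
    if d.get("schema") != REPORT_SCHEMA:
        raise ValueError(f"unexpected report schema {d.get('schema')!r}")
    return d
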