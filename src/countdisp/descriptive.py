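"""Descriptive association stage: count categories, cross-tabs, chi-square tests.

Council counts are binned into three categories ("<50", "51-200", ">200";
bins [0,50], [51,200], [201, inf) — the boundary 50 goes to the first bin so
the bins partition the non-negative integers).  Factor-by-category
contingency tables carry cell counts and percentages of the grand total, and
association is tested with the plain Pearson chi-square (no continuity
correction, no exact-test fallback; expected counts below 5 raise a warning
flag instead).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CATEGORY_LABELS",
    "categorize",
    "ContingencyTable",
    "contingency_table",
    "ChiSquareResult",
    "chi2_independence",
    "DispersionSummary",
    "dispersion_summary",
]

CATEGORY_LABELS = ("<50", "51-200", ">200")
_BIN_EDGES = (50, 200)  # [0,50], [51,200], [201, inf)


def categorize(counts) -> list:
    """Map non-negative integer counts to the three category labels."""
    counts = np.asarray(counts)
    if np.any(counts < 0) or np.any(counts != np.floor(counts)):
        raise ValueError("counts must be non-negative integers")
    idx = np.digitize(counts, [_BIN_EDGES[0] + 1, _BIN_EDGES[1] + 1])
    return [CATEGORY_LABELS[i] for i in idx]


@dataclass
class ContingencyTable:
    """Factor-level by count-category cross-tabulation."""

    row_factor: str
    row_levels: list
    col_categories: list
    counts: np.ndarray
    percentages: np.ndarray  # cell / grand total * 100
    total: int

    def to_dataframe(self) -> pd.DataFrame:
        """Cells formatted "count (pct)" in the style of published tables."""
        cells = [
            [
                f"{int(self.counts[i, j])} ({self.percentages[i, j]:.2f})"
                for j in range(len(self.col_categories))
            ]
            for i in range(len(self.row_levels))
        ]
        return pd.DataFrame(cells, index=self.row_levels, columns=self.col_categories)


def contingency_table(
    records: pd.DataFrame, factor: str, count_column: str
) -> ContingencyTable:
    """Cross-tabulate a categorical factor against count categories.

    Percentages are computed against the grand total (all tabulated
    councils), matching the convention of the study tables.
    """
    if factor not in records.columns:
        raise KeyError(f"factor column {factor!r} not found")
    df = records[[factor, count_column]].dropna()
    if len(df) == 0:
        raise ValueError("no complete records to tabulate")
    cats = pd.Categorical(
        categorize(df[count_column].to_numpy()), categories=list(CATEGORY_LABELS)
    )
    tab = pd.crosstab(df[factor], cats, dropna=False)
    tab = tab.reindex(columns=list(CATEGORY_LABELS), fill_value=0)
    counts = tab.to_numpy()
    total = int(counts.sum())
    return ContingencyTable(
        row_factor=factor,
        row_levels=list(tab.index),
        col_categories=list(CATEGORY_LABELS),
        counts=counts,
        percentages=counts / total * 100.0,
        total=total,
    )


@dataclass
class ChiSquareResult:
    statistic: float
    df: int
    p_value: float
    expected_counts: np.ndarray
    small_expected_warning: bool


def chi2_independence(table: ContingencyTable | np.ndarray) -> ChiSquareResult:
    """Pearson chi-square test of independence on an r x c table.

    No Yates correction and no exact-test fallback, even when expected
    counts fall below 5; the ``small_expected_warning`` flag reports that
    condition instead.
    """
    counts = table.counts if isinstance(table, ContingencyTable) else np.asarray(table)
    if counts.ndim != 2 or counts.shape[0] < 2 or counts.shape[1] < 2:
        raise ValueError("table must be at least 2 x 2")
    if counts.sum() <= 0:
        raise ValueError("empty table")
    if np.any(counts.sum(axis=0) == 0) or np.any(counts.sum(axis=1) == 0):
        raise ValueError("degenerate table: a row or column margin is zero")
    stat, p, df, expected = stats.chi2_contingency(counts, correction=False)
    return ChiSquareResult(
        statistic=float(stat),
        df=int(df),
        p_value=float(p),
        expected_counts=expected,
        small_expected_warning=bool(np.any(expected < 5)),
    )


@dataclass
class DispersionSummary:
    mean: float
    variance: float
    ratio: float  # variance / mean
    skewness: float
    histogram_bins: np.ndarray
    bin_edges: np.ndarray


def dispersion_summary(counts, bin_width: int = 50) -> DispersionSummary:
    """Sample mean, unbiased variance, variance/mean ratio, skewness, histogram.

    A ratio well above one (paired with positive skew) is the overdispersion
    signature that motivates moving beyond the Poisson model.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.size < 2:
        raise ValueError("need at least two observations")
    mean = float(counts.mean())
    var = float(counts.var(ddof=1))
    ratio = var / mean if mean > 0 and var > 0 else 0.0
    edges = np.arange(0, counts.max() + bin_width + 1, bin_width)
    hist, edges = np.histogram(counts, bins=edges)
    return DispersionSummary(
        mean=mean,
        variance=var,
        ratio=ratio,
        skewness=float(stats.skew(counts)) if var > 0 else 0.0,
        histogram_bins=hist,
        bin_edges=edges,
    )
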