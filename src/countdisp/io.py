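"""Reading and writing the council CSV schema.

One row per council:

    council_id, zone, residence, pplhiv_pct, population, gdp,
    n_facilities, pct_male, count_5_59, count_60plus

Count cells may be empty (council did not report); they are preserved as
missing and handled by complete-case filtering downstream.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .regression import RESIDENCE_LEVELS, ZONE_LEVELS

__all__ = ["CSV_COLUMNS", "read_council_csv", "write_council_csv"]

CSV_COLUMNS = [
    "council_id",
    "zone",
    "residence",
    "pplhiv_pct",
    "population",
    "gdp",
    "n_facilities",
    "pct_male",
    "count_5_59",
    "count_60plus",
]

_COUNT_COLUMNS = ("count_5_59", "count_60plus")


class SchemaError(ValueError):
    """The CSV does not match the documented council schema."""


def read_council_csv(path) -> pd.DataFrame:
    """Read and validate a council CSV; missing counts stay missing.

    Raises :class:`SchemaError` naming the offending column/value, or a
    ``ValueError`` naming the row, so a malformed file never flows silently
    into the analysis.
    """
    df = pd.read_csv(path)
    missing_cols = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing_cols:
        raise SchemaError(f"missing required column(s): {missing_cols}")

    bad_zone = set(df["zone"].dropna()) - set(ZONE_LEVELS)
    if bad_zone:
        raise SchemaError(f"unknown zone level(s): {sorted(bad_zone)}")
    bad_res = set(df["residence"].dropna()) - set(RESIDENCE_LEVELS)
    if bad_res:
        raise SchemaError(f"unknown residence level(s): {sorted(bad_res)}")

    for col in _COUNT_COLUMNS:
        vals = pd.to_numeric(df[col], errors="coerce")
        notna = vals.notna()
        if np.any(vals[notna] < 0) or np.any(vals[notna] != np.floor(vals[notna])):
            rows = df.index[notna & ((vals < 0) | (vals != np.floor(vals)))].tolist()
            raise ValueError(
                f"column {col!r} must hold non-negative integers; bad row(s): {rows}"
            )
        df[col] = vals.astype("Int64")
    return df[CSV_COLUMNS + [c for c in df.columns if c not in CSV_COLUMNS]]


def write_council_csv(records: pd.DataFrame, path) -> None:
    records.to_csv(path, index=False)
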