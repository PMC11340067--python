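import numpy as np
import pandas as pd
import pytest

from countdisp.regression import ModelSpec, build_design
from countdisp.synthetic import SyntheticConfig, generate

# zone x count-category tables for the two age groups, as published
# (rows: Central, Eastern, Lake, Northern, Southern, Southern Highlands, Western)
ZONE_TABLE_5_59 = np.array(
    [[11, 2, 2], [11, 5, 8], [21, 12, 3], [9, 17, 5], [16, 7, 0], [20, 9, 3], [12, 8, 3]]
)
ZONE_TABLE_60PLUS = np.array(
    [[12, 3, 0], [14, 6, 4], [28, 6, 2], [13, 14, 4], [22, 1, 0], [23, 8, 1], [16, 7, 0]]
)
RESIDENCE_TABLE_5_59 = np.array([[93, 38, 8], [7, 22, 16]])
RESIDENCE_TABLE_60PLUS = np.array([[112, 21, 6], [16, 24, 5]])


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240301)


@pytest.fixture(scope="session")
def council_records():
    """One study-shaped synthetic dataset (184 councils, GP counts, theta=2)."""
    records, truth = generate(SyntheticConfig(seed=11))
    return records, truth


@pytest.fixture(scope="session")
def small_design(rng):
    """A 20-row, 3-column random design with Poisson-scale counts."""
    X = np.column_stack([np.ones(20), rng.normal(size=20), rng.normal(size=20)])
    beta = np.array([1.0, 0.3, -0.2])
    y = rng.poisson(np.exp(X @ beta))
    return X, y


def records_to_design(records: pd.DataFrame, **spec_kwargs):
    return build_design(records, ModelSpec(**spec_kwargs))
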