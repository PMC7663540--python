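import numpy as np
import pandas as pd
import pytest

from blocksurv.io import OmicsMatrix, SurvivalOutcome, standardize


def make_matrix(values, layer_id="T", standardized=False, names=None):
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    df = pd.DataFrame(
        values,
        columns=names or [f"v{i}" for i in range(p)],
        index=[f"s{i:03d}" for i in range(n)],
    )
    return OmicsMatrix(layer_id=layer_id, data=df, standardized=standardized)


def std_matrix(values, layer_id="T", names=None):
    return standardize(make_matrix(values, layer_id=layer_id, names=names))


def make_survival(time, event, ids=None):
    time = np.asarray(time, dtype=float)
    ids = ids or [f"s{i:03d}" for i in range(len(time))]
    return SurvivalOutcome(list(ids), time, np.asarray(event))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def two_duplicate_pairs():
    """4 variables forming two exact-duplicate pairs (after standardization)."""
    r = np.random.default_rng(7)
    x = r.standard_normal(40)
    y = r.standard_normal(40)
    raw = np.column_stack([x, 2 * x + 3, y, -1 + 0.5 * y])
    return std_matrix(raw, names=["x1", "x2", "y1", "y2"])
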