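import numpy as np
import pytest

from ptsdml.cohort import CohortTable, TargetVector


@pytest.fixture
def toy_table():
    """3-subject table with one missing cell, from the imputation example."""
    vals = np.array([[0.0, 0.0, np.nan], [0.0, 0.0, 5.0], [9.0, 9.0, 1.0]])
    return CohortTable(
        values=vals,
        variable_names=["a", "b", "c"],
        variable_kinds=["continuous"] * 3,
        missing_mask=np.isnan(vals),
        subject_ids=["s1", "s2", "s3"],
    )


def make_table(values, kinds=None, names=None):
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    return CohortTable(
        values=values,
        variable_names=names or [f"v{j}" for j in range(p)],
        variable_kinds=kinds or ["continuous"] * p,
        missing_mask=np.isnan(values),
        subject_ids=[f"s{i}" for i in range(n)],
    )


def random_table(rng, n, p, missing_rate=0.0):
    values = rng.standard_normal((n, p))
    if missing_rate:
        mask = rng.random((n, p)) < missing_rate
        # keep every row and column partly observed
        mask[:, 0] = False
        values = np.where(mask, np.nan, values)
    return make_table(values)


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)
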