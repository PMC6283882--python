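import numpy as np
import pandas as pd
import pytest

from aabnet.cohort import CohortTable
from aabnet.simulate import DEFAULT_GROUP_SIZES, default_scenario, generate_cohort


def make_table(values: np.ndarray, analytes=None, groups=None, sexes=None, ages=None):
    """Small cohort-table builder for unit tests."""
    n, p = np.asarray(values).shape
    analytes = analytes or [f"A{i}" for i in range(p)]
    ids = pd.Index([f"s{i}" for i in range(n)], name="subject_id")
    meta = pd.DataFrame(
        {
            "group": groups if groups is not None else ["HD"] * n,
            "sex": sexes if sexes is not None else ["female"] * n,
            "age": ages if ages is not None else [50.0] * n,
        },
        index=ids,
    )
    vals = pd.DataFrame(np.asarray(values, dtype=float), index=ids, columns=analytes)
    return CohortTable(meta, vals)


@pytest.fixture(scope="session")
def scenario_truth():
    return default_scenario(seed=11)


@pytest.fixture(scope="session")
def scenario_cohort(scenario_truth):
    return generate_cohort(scenario_truth, DEFAULT_GROUP_SIZES, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
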