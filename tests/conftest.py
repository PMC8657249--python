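import numpy as np
import pandas as pd
import pytest

from stackprune.cohort import CohortTable, FeatureSchema


@pytest.fixture
def tiny_schema():
    return FeatureSchema(
        feature_names=("age", "grade", "site"),
        feature_kinds=("continuous", "ordinal", "categorical"),
        outcome_name="event",
    )


@pytest.fixture
def tiny_cohort(tiny_schema):
    rng = np.random.default_rng(0)
    n = 40
    records = pd.DataFrame(
        {
            "age": rng.normal(50, 10, n),
            "grade": rng.integers(1, 4, n),
            "site": rng.choice(["a", "b", "c"], n),
        }
    )
    labels = rng.integers(0, 2, n)
    labels[:2] = [0, 1]  # both classes guaranteed
    return CohortTable(schema=tiny_schema, records=records, labels=labels)


def make_separable_cohort(n=200, seed=0):
    """One continuous feature that perfectly separates the classes."""
    rng = np.random.default_rng(seed)
    labels = rng.integers(0, 2, n)
    x = labels * 10.0 + rng.uniform(0, 1, n)
    schema = FeatureSchema(("x",), ("continuous",), "event")
    return CohortTable(
        schema=schema, records=pd.DataFrame({"x": x}), labels=labels
    )


@pytest.fixture
def separable_cohort():
    return make_separable_cohort()
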