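import numpy as np
import pandas as pd
import pytest

from edvent.cohort import CSV_COLUMNS, Cohort, default_cohort_spec, generate_cohort


@pytest.fixture(scope="session")
def spec():
    return default_cohort_spec()


@pytest.fixture(scope="session")
def cohort_1049(spec):
    """Reference-size synthetic cohort, fixed seed."""
    return generate_cohort(spec, 1049, seed=0)


@pytest.fixture(scope="session")
def big_cohort(spec):
    """Large cohort for moment-recovery checks."""
    return generate_cohort(spec, 100_000, seed=7)


def make_cohort(records: list[dict]) -> Cohort:
    """Hand-build a tiny cohort; unspecified numerics default to 1.0."""
    rows = []
    for i, rec in enumerate(records):
        row = {c: 1.0 for c in CSV_COLUMNS}
        row.update({"id": i, "sex": "male", "age_group": ">60", "outcome": 0})
        row.update(rec)
        rows.append(row)
    df = pd.DataFrame(rows, columns=list(CSV_COLUMNS))
    df["sex"] = df["sex"].astype("string")
    df["age_group"] = df["age_group"].astype("string")
    df["outcome"] = df["outcome"].astype("Int64")
    return Cohort(df)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
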