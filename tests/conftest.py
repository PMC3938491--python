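import numpy as np
import pandas as pd
import pytest

from snpepi import Cohort, generate_cohort, mimic_params
from snpepi.simulate import discussion_cohort as _discussion_cohort


def make_cohort(**columns) -> Cohort:
    """Build a cohort from aligned column arrays, filling ids."""
    n = len(next(iter(columns.values())))
    df = pd.DataFrame({"id": [f"X{i:05d}" for i in range(n)], **columns})
    return Cohort(df)


def cohort_from_2xk(control_row, case_row, encoder) -> Cohort:
    """Expand a k x 2 exposure table into a cohort via per-level genotypes.

    ``encoder(level) -> (g1, g2)`` picks a representative genotype pair
    for each exposure level.
    """
    rows = []
    for status, counts in ((0, control_row), (1, case_row)):
        for level, n in enumerate(counts):
            g1, g2 = encoder(level)
            rows += [{"g1": g1, "g2": g2, "hiv": status}] * int(n)
    df = pd.DataFrame(rows)
    df.insert(0, "id", [f"K{i:05d}" for i in range(len(df))])
    return Cohort(df)


@pytest.fixture(scope="session")
def discussion_cohort():
    return _discussion_cohort()


@pytest.fixture(scope="session")
def mimic_cohort():
    cohort, _ = generate_cohort(mimic_params(), seed=7)
    return cohort


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)
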