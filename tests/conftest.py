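import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from iduinit import CohortConfig, generate_cohort

settings.register_profile("suite", deadline=None, max_examples=25, derandomize=True)
settings.load_profile("suite")


def make_counts_cohort(
    n_respondents: int,
    n_initiators: int,
    n_initiations: int,
    n_others: int = 2,
    sex: str = "M",
    ever: bool = False,
    career_years: int = 3,
    injected_past_year: bool = True,
) -> pd.DataFrame:
    """A homogeneous cohort matching given count totals exactly.

    Every initiator gets one initiation, with the remainder assigned to the
    first initiator, so subgroup totals are exact while individual counts
    stay valid.
    """
    assert 0 <= n_initiators <= n_respondents
    assert n_initiations >= n_initiators or n_initiators == 0
    k = np.zeros(n_respondents, dtype=int)
    if n_initiators:
        k[:n_initiators] = 1
        k[0] += n_initiations - n_initiators
    others = pd.array(
        [n_others if v > 0 else None for v in k], dtype="Int64"
    )
    return pd.DataFrame(
        {
            "id": pd.array([f"R{i:06d}" for i in range(n_respondents)], dtype="string"),
            "sex": pd.array([sex] * n_respondents, dtype="string"),
            "region": pd.array(["GGC"] * n_respondents, dtype="string"),
            "age_group": pd.array(["<35"] * n_respondents, dtype="string"),
            "career_years": np.full(n_respondents, career_years, dtype="int64"),
            "ever_incarcerated": np.full(n_respondents, ever),
            "injected_past_year": np.full(n_respondents, injected_past_year),
            "n_initiations_py": k.astype("int64"),
            "n_others_recent": others,
        }
    )


@pytest.fixture(scope="session")
def small_cohort():
    """A 1,200-respondent synthetic cohort shared across read-only tests."""
    records, truth = generate_cohort(CohortConfig(n_respondents=1200, seed=11))
    return records, truth


@pytest.fixture(scope="session")
def large_cohort():
    """A 50,000-respondent cohort for calibration and recovery checks."""
    records, truth = generate_cohort(CohortConfig(n_respondents=50_000, seed=202))
    return records, truth
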