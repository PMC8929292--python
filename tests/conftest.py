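import numpy as np
import pandas as pd
import pytest

from brainage import CohortConfig, FeatureTable, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """60 NC + 40 SZ, 60 features (12 informative), moderate noise."""
    cfg = CohortConfig(
        n_nc=60,
        n_sz=40,
        n_informative_linear=10,
        n_informative_quadratic=2,
        n_noise=48,
        noise_sd=15.0,
        seed=11,
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_nc(small_cohort):
    table, _ = small_cohort
    return table.select_group("NC")


@pytest.fixture()
def tiny_table():
    """Hand-built 6-subject table over 3 DTI features."""
    rng = np.random.default_rng(7)
    names = ["DTI:FA:1", "DTI:FA:2", "DTI:MD:1"]
    df = pd.DataFrame(
        {
            "subject_id": [f"s{i}" for i in range(6)],
            "group": ["NC"] * 4 + ["SZ"] * 2,
            "age": [25.0, 30.0, 40.0, 55.0, 33.0, 48.0],
            "gender": [0, 1, 0, 1, 1, 0],
        }
    )
    for n in names:
        df[n] = rng.normal(size=6)
    return FeatureTable.from_dataframe(df)
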