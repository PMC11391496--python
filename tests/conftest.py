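import numpy as np
import pandas as pd
import pytest

from vfnet.cohort import CohortConfig, make_region_table
from vfnet.design import make_design
from vfnet.timeseries import RoiTimeSeries


@pytest.fixture(scope="session")
def design():
    return make_design()


@pytest.fixture(scope="session")
def small_regions():
    """A 12-region table with two left cortices and a named seed ROI."""
    named = {"L_seed": ("left-temporal", 0), "L_front": ("left-frontal", 0)}
    return make_region_table(
        {"left-frontal": 4, "left-temporal": 4, "right-frontal": 2, "right-temporal": 2},
        roi_names=("L_seed", "L_front"),
        named=named,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def noise_series(rng):
    data = rng.standard_normal((8, 200))
    return RoiTimeSeries(data, tr_s=1.0, region_labels=[f"r{i}" for i in range(8)],
                         subject_id="sub-x", prepped=True)


def null_covariates(rng, n):
    return pd.DataFrame(
        {
            "age": rng.normal(35, 10, n),
            "sex": rng.integers(0, 2, n).astype(float),
            "education": rng.normal(12, 3, n),
            "moca": rng.normal(26, 2, n),
        }
    )


@pytest.fixture(scope="session")
def tiny_cohort_config():
    return CohortConfig(
        group_sizes={"HC": 3, "TLE-HS": 3, "TLE-NHS": 3},
        seed=9,
    )
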