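import numpy as np
import pandas as pd
import pytest

from adtime import GroupCurveParams, gen_amyloid_cohort, gen_cognitive_cohort


@pytest.fixture(scope="session")
def default_curve() -> GroupCurveParams:
    """The generator's default decline curve (has both curvature terms)."""
    _, truth = gen_cognitive_cohort(1, seed=0)
    return GroupCurveParams(**truth.params["curve"])


@pytest.fixture(scope="session")
def small_cognitive_cohort():
    """60 noisy subjects with known shifts: shared across c-time tests."""
    cohort, truth = gen_cognitive_cohort(60, noise_sd=0.05, seed=123)
    return cohort, truth


@pytest.fixture(scope="session")
def amyloid_cohort():
    """150 sigmoidal amyloid accumulators with known onset ages."""
    cohort, truth = gen_amyloid_cohort(150, noise_sd=0.02, seed=77)
    return cohort, truth


def make_long(records) -> pd.DataFrame:
    return pd.DataFrame(
        records, columns=["subject_id", "age", "t_years", "value", "modality"]
    )


@pytest.fixture
def rng():
    return np.random.default_rng(2026)
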