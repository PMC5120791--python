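import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import cbfsurrogate as cs

settings.register_profile(
    "suite", derandomize=True, max_examples=30,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def default_cohort() -> pd.DataFrame:
    """The 88-patient / 261-measurement default cohort (planted effects)."""
    return cs.generate_cohort(cs.CohortConfig(seed=20))


@pytest.fixture(scope="session")
def null_cohort() -> pd.DataFrame:
    """Default-sized cohort with CBF independent of all predictors."""
    cfg = cs.CohortConfig(effect_spec=cs.EffectSpec(mode="null"), seed=21)
    return cs.generate_cohort(cfg)


def random_numeric_table(rng, n_rows, n_cols):
    """Small all-numeric table with continuous predictors and response,
    as used by the brute-force CART comparisons."""
    X = rng.random((n_rows, n_cols))
    y = rng.random(n_rows) * 10
    df = pd.DataFrame(X, columns=[f"x{j}" for j in range(n_cols)])
    return df, y
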