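import numpy as np
import pandas as pd
import pytest

import rdcea
from rdcea.imputation import CompletedDatasetStack, ImputationConfig


@pytest.fixture(scope="session")
def small_cohort():
    """A 400-participant cohort with default (MAR) missingness."""
    return rdcea.simulate_cohort(rdcea.CohortConfig(n_participants=400, seed=11))


@pytest.fixture(scope="session")
def small_analysis(small_cohort):
    return rdcea.build_analysis_dataset(small_cohort)


@pytest.fixture(scope="session")
def small_stack(small_analysis):
    return rdcea.impute_cohort(
        small_analysis, ImputationConfig(m_imputations=4, seed=11)
    )


def make_adjusted_dataset(n, delta_cost, delta_qaly, seed,
                          treated_frac=0.154, cost_sd=120.0, qaly_sd=0.02):
    """Analysis-ready dataset with known adjusted incremental effects.

    Confounding (treated participants start with lower utility and higher
    baseline costs) runs entirely through the adjusted covariates, so the
    covariate-adjusted arm coefficients identify ``delta_cost`` and
    ``delta_qaly`` exactly in expectation.
    """
    rng = np.random.default_rng(seed)
    n_sg = max(2, int(round(n * treated_frac)))
    arm = np.array(["SG"] * n_sg + ["SoC"] * (n - n_sg))
    t = (arm == "SG").astype(float)
    u0 = np.clip(0.75 - 0.10 * t + rng.normal(0, 0.08, n), -0.594, 1.0)
    c0 = np.exp(rng.normal(3.0 + 0.5 * t, 0.5, n))
    cost = 20 + 0.3 * c0 - 50 * u0 + delta_cost * t + rng.normal(0, cost_sd, n)
    qaly = 0.05 + 0.4 * u0 + delta_qaly * t + rng.normal(0, qaly_sd, n)
    return pd.DataFrame({
        "id": np.arange(n),
        "arm": arm,
        "age_years": 65 + rng.gamma(2, 4.5, n),
        "sex": np.where(rng.random(n) < 0.48, "female", "male"),
        "utility_baseline": u0,
        "baseline_total_cost": c0,
        "total_cost_6m": cost,
        "qaly": qaly,
    })


def stack_of(*datasets, seed=0):
    """Wrap completed dataframes as a stack with an all-observed mask."""
    mask = datasets[0][[]].isna()
    return CompletedDatasetStack(datasets=list(datasets), mask=mask,
                                 config=ImputationConfig(seed=seed), seed=seed)
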