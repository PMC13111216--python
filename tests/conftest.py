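import numpy as np
import pandas as pd
import pytest

from mmpcr import FeatureTable, CohortOutcomes, SimConfig, simulate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture(scope="session")
def default_cohort():
    """One study-shaped synthetic cohort, shared read-only across tests."""
    return simulate_cohort(SimConfig(seed=11))


def make_table(X, feature_ids, prefix="s"):
    """FeatureTable from a raw matrix and explicit feature ids."""
    n = X.shape[0]
    df = pd.DataFrame(
        X, index=pd.Index([f"{prefix}{i}" for i in range(n)], name="subject_id"),
        columns=feature_ids,
    )
    return FeatureTable(df)


def make_groups(table, n_pwh):
    """Outcome frame labelling the last n_pwh subjects as PWH."""
    ids = table.subject_ids
    groups = ["control"] * (len(ids) - n_pwh) + ["PWH"] * n_pwh
    return CohortOutcomes(
        pd.DataFrame({"subject_id": ids, "group": groups, "z_baseline": 0.0})
    )
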