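import numpy as np
import pandas as pd
import pytest

from dagoat.io import CohortDataset, DynamicPanel


def make_cohort(values, mask, onsets, last_observed=None, peri=None, horizon=None):
    """Build a small CohortDataset from raw arrays (helper for unit tests)."""
    values = np.asarray(values, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    n, p, H = values.shape
    patients = [f"p{i}" for i in range(n)]
    feats = [f"f{k}" for k in range(p)]
    panel = DynamicPanel(values, mask, patients, feats, horizon or H)
    if last_observed is None:
        last_observed = [H] * n
    if peri is None:
        peri = pd.DataFrame(index=patients)
    else:
        peri = pd.DataFrame(peri, index=patients)
    outcomes = pd.DataFrame(
        {
            "onset_day": pd.array(
                [o if o is not None else pd.NA for o in onsets], dtype="Int64"
            ),
            "last_observed_day": list(last_observed),
        },
        index=patients,
    )
    return CohortDataset(panel, peri, outcomes)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def clinical_cohort():
    """Medium synthetic clinical cohort shared by the slower tests."""
    from dagoat.simulation import generate_clinical_fixture

    cohort, truth = generate_clinical_fixture(n_patients=500, seed=1)
    return cohort, truth


@pytest.fixture(scope="session")
def sim_cohort_smooth():
    from dagoat.simulation import SimScenario, simulate_cohort

    scen = SimScenario("complex", "smooth", 0.0, n=400, seed=11)
    return simulate_cohort(scen)
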