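"""Shared fixtures: small hand-checkable survival fixtures and the default
synthetic cohort (session-scoped; simulation is deterministic)."""

import numpy as np
import pandas as pd
import pytest

from tlsig import (ClinicalTable, compute_tls_score, default_cohort_spec,
                   simulate_cohort)


@pytest.fixture
def five_subject_clinical():
    """Times 1..5, events at 2, 3, 5: S = 0.75, 0.5, 0 by hand product-limit."""
    return ClinicalTable(
        pd.DataFrame(
            {"time": [1.0, 2.0, 3.0, 4.0, 5.0], "event": [0, 1, 1, 0, 1]},
            index=pd.Index(list("abcde"), name="sample_id"),
        )
    )


@pytest.fixture
def tied_clinical_20():
    """20 subjects with integer (tied) times for Efron-ties oracle checks."""
    rng = np.random.default_rng(11)
    time = rng.integers(1, 8, 20).astype(float)
    event = rng.integers(0, 2, 20)
    event[0] = 1
    x = rng.normal(size=20)
    ids = [f"s{i:02d}" for i in range(20)]
    clin = ClinicalTable(
        pd.DataFrame({"time": time, "event": event},
                     index=pd.Index(ids, name="sample_id"))
    )
    cov = pd.DataFrame({"x": x}, index=ids)
    return clin, cov


@pytest.fixture(scope="session")
def default_cohort():
    return simulate_cohort(default_cohort_spec(seed=1))


@pytest.fixture(scope="session")
def default_scores(default_cohort):
    return compute_tls_score(default_cohort.expression)
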