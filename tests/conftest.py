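import logging

import numpy as np
import pandas as pd
import pytest

import lactpair as lp

logging.getLogger("lactpair").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def small_cohort():
    """Tiny null cohort for plumbing tests (20 genes x 60 samples)."""
    return lp.generate_cohort(lp.default_config(20, 60, seed=11))


@pytest.fixture(scope="session")
def planted_cohort():
    """Cohort with five planted pair effects (|beta| = 1), n = 300."""
    return lp.generate_cohort(lp.default_config(50, 300, n_planted=5, beta=1.0, seed=7))


@pytest.fixture(scope="session")
def planted_result(planted_cohort):
    """Trained signature on the planted cohort (shared across tests)."""
    return lp.train_lrgpi(planted_cohort.expression, planted_cohort.clinical,
                          lp.PipelineConfig(), covariates=["age"])


def make_clinical(times, events, ids=None, **extra):
    ids = ids or [f"s{i}" for i in range(len(times))]
    return pd.DataFrame(
        {"time_months": np.asarray(times, dtype=float),
         "event": np.asarray(events, dtype=int), **extra},
        index=pd.Index(ids, name="sample_id"),
    )
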