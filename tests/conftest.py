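import numpy as np
import pytest
from hypothesis import settings

import somaticsurv as ss

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=30)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)


def random_outcome(rng, n, tie_fraction=0.0, censor_fraction=0.4):
    """A small random censored outcome; optionally with tied times."""
    t = rng.exponential(20.0, n) + 0.01
    if tie_fraction > 0:
        t = np.round(t) + 1.0
    e = (rng.random(n) > censor_fraction).astype(int)
    if e.sum() == 0:
        e[0] = 1
    return ss.SurvivalOutcome(t, e)


@pytest.fixture(scope="session")
def strong_cohort():
    """Synthetic cohort with a clear prognostic signal (shared across tests)."""
    cfg = ss.SimConfig(n_patients=300, n_genes=100, causal_genes=5,
                       causal_log_hr=1.0, seed=8)
    return ss.generate_cohort(cfg)


@pytest.fixture(scope="session")
def strong_filtered(strong_cohort):
    return ss.filter_rare_genes(strong_cohort.mutation_matrix, 5)


@pytest.fixture(scope="session")
def strong_cv(strong_cohort, strong_filtered):
    return ss.loocv_risk_scores(strong_filtered, strong_cohort.os_outcome)
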