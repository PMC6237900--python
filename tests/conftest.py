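import numpy as np
import pandas as pd
import pytest

from seprogadic import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Reduced but structurally complete cohort shared across tests."""
    cfg = SimulationConfig(
        n_patients=120,
        n_batches=6,
        n_md_proteins=12,
        n_nd_proteins=8,
        effect_sizes=(0.8, 0.7, -0.7),
        seed=11,
    )
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def noise_free_cohort():
    """Cohort with technical noise and biological NP variation switched off."""
    cfg = SimulationConfig(
        n_patients=60,
        n_batches=4,
        n_md_proteins=6,
        n_nd_proteins=4,
        n_np_candidates=6,
        n_np_confounded=0,
        effect_sizes=(0.8, 0.7, -0.7),
        technical_cv=0.0,
        np_biological_sd=0.0,
        seed=5,
    )
    return simulate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_survival(rng, n=200, coef=0.0, censor=0.3, scale=50.0):
    """Simple PH data with one normal covariate of log-hazard ``coef``."""
    x = rng.standard_normal(n)
    t = rng.exponential(scale * np.exp(-coef * x))
    c = rng.exponential(scale / max(censor, 1e-9)) if censor > 0 else np.full(n, np.inf)
    time = np.minimum(t, c)
    event = (t <= c).astype(int)
    return time, event, x
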