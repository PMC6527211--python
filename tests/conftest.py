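"""Shared fixtures: small synthetic samples and the session-wide study run."""

from types import SimpleNamespace

import numpy as np
import pytest
from scipy.special import expit

import rarepen as rp

#: replicates fitted once per session for the full-design selection checks
N_STUDY_REPLICATES = 20
STUDY_SEED = 0


def make_sample(n=800, p=6, seed=0, beta=None, prevalences=None,
                intercept=0.0):
    """A small independent-Bernoulli cohort for estimator unit tests."""
    rng = np.random.default_rng(seed)
    if prevalences is None:
        prevalences = np.full(p, 0.3)
    prevalences = np.asarray(prevalences, dtype=float)
    X = rng.binomial(1, prevalences, size=(n, p)).astype(np.int8)
    if beta is None:
        beta = np.zeros(p)
    eta = intercept + X @ np.asarray(beta, dtype=float)
    y = (rng.random(n) < expit(eta)).astype(np.int8)
    return rp.CohortSample(X=X, y=y)


@pytest.fixture
def noise_sample():
    """Outcome independent of all covariates."""
    return make_sample(n=600, p=5, seed=42)


@pytest.fixture
def signal_sample():
    """One strong predictor among noise."""
    return make_sample(n=2000, p=5, seed=7, beta=[1.5, 0, 0, 0, 0])


@pytest.fixture(scope="session")
def study():
    """Replicates of the full 50-exposure case-control design, all methods.

    Generated once per session; every replicate uses the study-scale
    population (100,000 subjects, 5,000 cases + 5,000 controls).
    """
    cfg = rp.ExperimentConfig(n_replicates=N_STUDY_REPLICATES,
                              master_seed=STUDY_SEED)
    tables, manifest, records = rp.run_experiment(cfg)
    return SimpleNamespace(records=records, tables=tables,
                           spec=records[0].truth, config=cfg)
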