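"""Shared fixtures: small proportional-hazards datasets and synthetic cohorts."""

import numpy as np
import pytest

from tepcox import SimulationConfig, generate_cohort
from tepcox._containers import ExpressionMatrix


def make_ph_data(n, beta, seed, scale=30.0, shape=1.0, censor_mean=60.0):
    """Direct Weibull proportional-hazards draw for unit tests.

    Returns (X, observed time, event) with X standard normal and censoring
    exponential with the given mean.
    """
    rng = np.random.default_rng(seed)
    beta = np.asarray(beta, dtype=float)
    X = rng.normal(size=(n, len(beta)))
    eta = X @ beta
    t_event = scale * (-np.log(rng.uniform(size=n)) / np.exp(eta)) ** (1.0 / shape)
    c = rng.exponential(censor_mean, size=n)
    time = np.maximum(np.minimum(t_event, c), 1e-9)
    event = (t_event <= c).astype(int)
    return X, time, event


def expr_from_array(X, prefix="g"):
    """Wrap a samples x features array as a normalized ExpressionMatrix."""
    n, p = X.shape
    return ExpressionMatrix(
        gene_ids=[f"{prefix}{j}" for j in range(p)],
        sample_ids=[f"s{i}" for i in range(n)],
        values=X.T,
        is_normalized=True,
    )


@pytest.fixture(scope="session")
def small_cohort():
    """250 samples x 400 genes, 10 signal genes — shared across tests."""
    config = SimulationConfig(
        n_samples=250, n_genes=400, n_signal=10, signal_effect=0.5, seed=42
    )
    return generate_cohort(config)


@pytest.fixture(scope="session")
def null_cohort():
    """No signal, no clinical effects: every gene is noise."""
    config = SimulationConfig(
        n_samples=200, n_genes=300, n_signal=0, signal_effect=0.0, seed=7
    )
    return generate_cohort(config)
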