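import numpy as np
import pandas as pd
import pytest

from homapanel import CohortSpec, PhenotypeParams, make_fixtures, simulate_cohort
from homapanel.preprocess import autoscale, dichotomize_by_median


@pytest.fixture(scope="session")
def fixture_cohorts():
    """Deterministic tiny training/validation cohorts (n = 60/30, p = 25)."""
    return make_fixtures(seed=0)


@pytest.fixture(scope="session")
def small_planted():
    """A small complete planted regression design for fast model tests.

    n = 120, p = 15, three independent signal features with coefficients
    (1.2, -1.0, 0.9) on the latent outcome; binary labels from the median
    split.  Returns (X, y_binary, latent, signal_names).
    """
    rng = np.random.default_rng(42)
    n, p = 120, 15
    X = pd.DataFrame(
        rng.standard_normal((n, p)), columns=[f"m{j:02d}" for j in range(p)]
    )
    X, _, _ = autoscale(X)
    beta = np.zeros(p)
    sig = [0, 7, 14]
    for j, b in zip(sig, (1.2, -1.0, 0.9)):
        beta[j] = b
    latent = X.to_numpy() @ beta + rng.standard_normal(n)
    y, _ = dichotomize_by_median(latent)
    return X, y, latent, [f"m{j:02d}" for j in sig]


@pytest.fixture(scope="session")
def null_cohort_500():
    """A complete cohort with no planted signal, n = 500, for invariants."""
    spec = CohortSpec(
        n_subjects=500,
        n_metabolites=60,
        n_high_missing=0,
        n_signal=0,
        block_structure=((10, 0.6), (8, 0.4)),
        missing_rate=0.0,
        phenotype_params=PhenotypeParams.satin_like(),
        seed=7,
    )
    return simulate_cohort(spec)
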