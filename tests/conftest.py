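import numpy as np
import pytest

from nascentfret import (
    ConditionKey,
    GenerativeParams,
    aggregate_profile,
    compute_experiment_fret,
    reference_truth_table,
    simulate_experiment_series,
)


@pytest.fixture(scope="session")
def truth():
    return reference_truth_table()


@pytest.fixture(scope="session")
def quiet_params():
    """Deterministic generator settings (no spectral or counting noise)."""
    return GenerativeParams().quiet()


@pytest.fixture(scope="session")
def noisy_params():
    """Study-condition noise: 2% spectral CV, Poisson counts."""
    return GenerativeParams()


@pytest.fixture(scope="session")
def wt624(truth):
    """Wild type, acceptor at Arg487, truncation 624 (reported mean 39.6%)."""
    return ConditionKey("WT", 487, 624)


def measure_series(key, truth, n, seed, params):
    """Simulate n replicates of a condition and aggregate their FRET."""
    bundles = simulate_experiment_series(key, truth, n, seed, params=params)
    return aggregate_profile([compute_experiment_fret(b) for b in bundles])
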