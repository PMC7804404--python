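import numpy as np
import pandas as pd
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture
def two_group_samples():
    """2 donors x 2 conditions, one lineage."""
    return pd.DataFrame(
        {
            "sample": ["s1", "s2", "s3", "s4"],
            "condition": ["resting", "activated", "resting", "activated"],
            "donor": ["d1", "d1", "d2", "d2"],
        }
    )


def nb_counts(rng, mu, dispersion):
    if dispersion <= 0:
        return rng.poisson(mu)
    r = 1.0 / dispersion
    return rng.negative_binomial(r, r / (r + mu))


@pytest.fixture
def nb_sampler():
    return nb_counts
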