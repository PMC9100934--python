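import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import glycomicrobe as g

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_cfg():
    """Desk-sized simulation config shared across module tests."""
    return g.SynthConfig(
        n_individuals=40, n_taxa=30, n_contaminants_per_mechanism=2,
        n_replicated_pairs=10, seed=101,
        planted_effects=(("genus_003", "P7", 1.0),), prs_trait="P7")


@pytest.fixture(scope="session")
def small_data(small_cfg):
    counts, samples, glycome, covariates, prs, truth = g.simulate_all(small_cfg)
    return dict(counts=counts, samples=samples, glycome=glycome,
                covariates=covariates, prs=prs, truth=truth)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


@pytest.fixture()
def toy_peaks():
    """4-peak relative-area table for harmonization toys."""
    return pd.DataFrame(
        [[0.1, 0.2, 0.3, 0.4], [0.25, 0.25, 0.25, 0.25]],
        index=["s1", "s2"], columns=["a", "b", "c", "d"])
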