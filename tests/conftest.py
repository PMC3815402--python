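import numpy as np
import pandas as pd
import pytest

from syncopebayes import CardiacSyncopeModel, datasets
from syncopebayes.simulate import POPULATIONS, PopulationSpec


@pytest.fixture(scope="session")
def pooled():
    return datasets.load_pooled_tables()


@pytest.fixture(scope="session")
def results():
    """Model fitted from the bundled literature fixtures."""
    return CardiacSyncopeModel.from_literature().fit()


@pytest.fixture(scope="session")
def population_specs():
    return {p: PopulationSpec.from_published(p) for p in POPULATIONS}


@pytest.fixture(scope="session")
def calgary_spec(population_specs):
    return population_specs["calgary"]


def make_labelled_scores(rng, n_cardiac, n_noncardiac, tie_grid=None):
    """Random posterior-like scores with optional ties for metric tests."""
    x = rng.random(n_cardiac) ** 0.5  # skew cardiac scores upward
    y = rng.random(n_noncardiac) ** 2.0
    if tie_grid:
        x = np.round(x * tie_grid) / tie_grid
        y = np.round(y * tie_grid) / tie_grid
    scores = np.concatenate([x, y])
    labels = np.array(["cardiac"] * n_cardiac + ["noncardiac"] * n_noncardiac)
    return scores, labels
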