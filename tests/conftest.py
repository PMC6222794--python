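import numpy as np
import pandas as pd
import pytest

import comsakit as ck


@pytest.fixture
def molecules():
    """Default congeneric series (20 molecules, shared 15-atom scaffold)."""
    return ck.make_molecule_set(ck.SyntheticSpec(seed=7))


@pytest.fixture
def small_molecules():
    """A small, fast series for SOM/field tests."""
    return ck.make_molecule_set(
        ck.SyntheticSpec(n_molecules=4, n_scaffold_atoms=6,
                         n_substituent_atoms=2, seed=3))


@pytest.fixture
def response_data():
    """Default receptor-response dataset with planted truth."""
    truth = ck.ResponseTruth()
    matrix, activities = ck.make_response_dataset(20, truth, seed=11)
    return matrix, activities, truth


def random_linear_problem(rng, n, p, noise=0.0):
    X = rng.normal(size=(n, p))
    beta = rng.normal(size=p)
    y = X @ beta + (rng.normal(size=n) * noise if noise else 0.0)
    return X, y, beta
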