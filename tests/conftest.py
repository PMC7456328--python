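import logging

import numpy as np
import pytest

from adrml import SyntheticParams, simulate
from adrml.io import FeatureTable, ResponseMatrix, SimilarityMatrix


@pytest.fixture(autouse=True)
def _quiet_warnings(caplog):
    # solver safeguard warnings are expected noise in stress tests
    logging.getLogger("adrml.factorization").setLevel(logging.ERROR)
    yield


@pytest.fixture(scope="session")
def small_dataset():
    """A 30x8 rank-2 synthetic dataset shared by read-only tests."""
    return simulate(
        SyntheticParams(
            n=30, m=8, n_genes=60, k=2, sigma=0.05, missing_fraction=0.2,
            n_tissues=3, seed=7,
        )
    )


def random_response(rng, n, m, missing=0.0):
    values = rng.standard_normal((n, m))
    mask = rng.random((n, m)) >= missing
    values = np.where(mask, values, np.nan)
    return ResponseMatrix(
        [f"c{i}" for i in range(n)],
        [f"d{j}" for j in range(m)],
        values,
        mask,
    )


def random_raw_similarity(rng, ids, low=0.1, high=0.9):
    """A symmetric nonnegative raw-similarity-shaped matrix (diag 1)."""
    n = len(ids)
    A = rng.uniform(low, high, size=(n, n))
    S = (A + A.T) / 2
    np.fill_diagonal(S, 1.0)
    return SimilarityMatrix(list(ids), S)


def random_binary_table(rng, n, p, kind="MUT"):
    values = (rng.random((n, p)) < 0.4).astype(float)
    # guarantee nonzero support per row
    for i in np.nonzero(values.sum(axis=1) == 0)[0]:
        values[i, rng.integers(p)] = 1.0
    return FeatureTable([f"e{i}" for i in range(n)], [f"f{j}" for j in range(p)], values, kind)
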