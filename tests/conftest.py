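import numpy as np
import pandas as pd
import pytest

from raretest.core_types import GenotypeMatrix, GeneSet, Pedigree


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_matrix():
    """6 samples x 5 variants, hand-written counts (already minor-oriented).

    Per-variant MAFs: v1 1/12, v2 3/12, v3 0 (monomorphic), v4 2/12,
    v5 missing for one sample -> 2/10.
    """
    counts = np.array(
        [
            # v1 v2 v3 v4 v5
            [0, 1, 0, 0, 0],
            [1, 0, 0, 2, 1],
            [0, 1, 0, 0, 0],
            [0, 0, 0, 0, np.nan],
            [0, 1, 0, 0, 1],
            [0, 0, 0, 0, 0],
        ],
        dtype=float,
    )
    return GenotypeMatrix(
        [f"S{i}" for i in range(1, 7)], ["v1", "v2", "v3", "v4", "v5"], counts
    )


@pytest.fixture
def small_geneset(small_matrix):
    return GeneSet({"G1": ["v1", "v2", "v3", "v4", "v5"], "G2": ["v1", "v4"]},
                   small_matrix)


@pytest.fixture
def trio_pedigree():
    rows = [
        ("F1", "dad", None, None, 1),
        ("F1", "mom", None, None, 2),
        ("F1", "kid", "dad", "mom", 1),
    ]
    return Pedigree(pd.DataFrame(rows, columns=["fid", "iid", "father", "mother", "sex"]))


@pytest.fixture
def sib_pedigree():
    rows = [
        ("F1", "p1", None, None, 1),
        ("F1", "p2", None, None, 2),
        ("F1", "s1", "p1", "p2", 1),
        ("F1", "s2", "p1", "p2", 2),
        ("F2", "q1", None, None, 1),
    ]
    return Pedigree(pd.DataFrame(rows, columns=["fid", "iid", "father", "mother", "sex"]))


def ols_loglik(y, X):
    """Independent closed-form Gaussian ML log-likelihood of y on X.

    Normal-equations least squares and the analytic profile likelihood
    -n/2 (log(2 pi RSS/n) + 1); used as an oracle against the package's
    fitted values.
    """
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    beta = np.linalg.lstsq(X, y, rcond=None)[0]
    r = y - X @ beta
    rss = float(r @ r)
    n = len(y)
    return -0.5 * n * (np.log(2 * np.pi * rss / n) + 1.0)
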