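import numpy as np
import pytest

from methdecon.containers import LMCMatrix, MethylationMatrix, ProportionMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_instance(rng):
    """Random conforming (D, T, A) triple of shape 10 x 4 x 3 samples."""
    m, k, n = 10, 4, 3
    T = rng.uniform(0, 1, (m, k))
    A = rng.dirichlet(np.ones(k), size=n).T
    D = np.clip(T @ A + rng.normal(0, 0.02, (m, n)), 0, 1)
    return MethylationMatrix(D), LMCMatrix(T), ProportionMatrix(A)


def brute_force_objective(D, T, A, lam):
    """Element-wise loop evaluation of the regularized criterion."""
    m, n = D.shape
    k = T.shape[1]
    rss = 0.0
    for i in range(m):
        for j in range(n):
            pred = sum(T[i, s] * A[s, j] for s in range(k))
            rss += (D[i, j] - pred) ** 2
    pen = lam * sum(T[i, s] * (1 - T[i, s]) for i in range(m) for s in range(k))
    return rss + pen
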