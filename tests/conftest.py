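import numpy as np
import pytest
from hypothesis import settings

from distimpute import MaskedDistanceMatrix

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


def random_masked_matrix(
    rng: np.random.Generator, n: int, n_missing: int
) -> MaskedDistanceMatrix:
    """Random valid symmetric matrix in [0, 1] with n_missing masked pairs."""
    a = rng.random((n, n))
    a = (a + a.T) / 2.0
    np.fill_diagonal(a, 0.0)
    mask = np.zeros((n, n), dtype=bool)
    pairs = [(i, j) for i in range(1, n) for j in range(i)]
    for idx in rng.choice(len(pairs), size=n_missing, replace=False):
        i, j = pairs[int(idx)]
        mask[i, j] = mask[j, i] = True
    return MaskedDistanceMatrix(tuple(f"t{i}" for i in range(n)), a, mask)


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def quartet_matrix():
    """Additive quartet from tree ((A:1,B:1):1,(C:1,D:1)): AB|CD."""
    values = np.array(
        [
            [0.0, 2.0, 3.0, 3.0],
            [2.0, 0.0, 3.0, 3.0],
            [3.0, 3.0, 0.0, 2.0],
            [3.0, 3.0, 2.0, 0.0],
        ]
    )
    return MaskedDistanceMatrix(("A", "B", "C", "D"), values)
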