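import numpy as np
import pytest

from dnilmf import DTIDataset, SyntheticSpec, generate


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_dataset():
    """5 drugs x 4 targets with hand-set interactions and similarities."""
    rng = np.random.default_rng(0)
    Y = np.array(
        [
            [1, 0, 0, 1],
            [0, 1, 0, 0],
            [1, 1, 0, 0],
            [0, 0, 1, 0],
            [0, 1, 1, 0],
        ],
        dtype=float,
    )
    def sim(n):
        A = rng.random((n, n))
        S = (A + A.T) / 2 * 0.8
        np.fill_diagonal(S, 1.0)
        return S
    return DTIDataset(
        drug_ids=[f"D{i}" for i in range(5)],
        target_ids=[f"T{j}" for j in range(4)],
        Y=Y,
        S_cs=sim(5),
        S_ts=sim(4),
    )


@pytest.fixture(scope="session")
def small_synthetic():
    """A 40x30 rank-3 synthetic dataset shared across tests."""
    return generate(
        SyntheticSpec(n_drugs=40, n_targets=30, rank=3,
                      target_sparsity=0.05, similarity_noise=0.05, seed=11)
    )


def random_similarity(rng, n, scale=0.9):
    """Random symmetric unit-diagonal similarity matrix in [0, 1]."""
    A = rng.random((n, n)) * scale
    S = (A + A.T) / 2
    np.fill_diagonal(S, 1.0)
    return S
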