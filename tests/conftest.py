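import numpy as np
import pytest

from cozine import CountTable, HurdleParameters


@pytest.fixture
def small_counts() -> CountTable:
    values = np.array(
        [
            [2.0, 2.0, 0.0, 4.0],
            [1.0, 0.0, 1.0, 2.0],
            [5.0, 5.0, 5.0, 5.0],
            [0.0, 3.0, 0.0, 1.0],
        ]
    )
    return CountTable(values=values, sample_ids=("a", "b", "c", "d"), taxon_ids=("t1", "t2", "t3", "t4"))


@pytest.fixture
def p2_params() -> HurdleParameters:
    """Small two-node parameter set with all interaction types present."""
    return HurdleParameters(
        G=np.array([[0.5, 0.2], [0.2, -0.3]]),
        H=np.array([[1.0, 0.1], [-0.2, 0.8]]),
        K=np.array([[2.0, 0.3], [0.3, 1.5]]),
    )


def random_params(p: int, rng: np.random.Generator, scale: float = 0.3) -> HurdleParameters:
    """Random valid (G, H, K) with diagonally dominant (hence PD) K."""
    G = rng.uniform(-scale, scale, (p, p))
    G = (G + G.T) / 2
    H = rng.uniform(-scale, scale, (p, p))
    K = rng.uniform(-scale, scale, (p, p))
    K = (K + K.T) / 2
    np.fill_diagonal(K, np.abs(K).sum(axis=0) - np.abs(np.diag(K)) + 0.5)
    return HurdleParameters(G=G, H=H, K=K)
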