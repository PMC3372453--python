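import numpy as np
import pytest

from ncinet import (
    CommunityPartition,
    GRNMatrix,
    simulate_expression,
    test1_network,
)


@pytest.fixture(scope="session")
def bench14() -> GRNMatrix:
    """The canonical 14-gene, 27-interaction benchmark network."""
    return test1_network()


@pytest.fixture(scope="session")
def bench14_communities() -> CommunityPartition:
    """Planted communities of the 14-gene benchmark (0-based indices)."""
    return CommunityPartition(
        groups=[[0, 1, 2, 3, 4], [5, 6, 7, 8, 9]], outliers=[10, 11, 12, 13]
    )


@pytest.fixture()
def cyclic5() -> GRNMatrix:
    """Slowly decaying signed 5-gene ring; fully identifiable from one run."""
    A = np.zeros((5, 5))
    for i, s in enumerate([1, -1, 1, 1, -1]):
        A[i, (i + 1) % 5] = 0.95 * s
    return GRNMatrix(A)


@pytest.fixture(scope="session")
def expr14(bench14):
    return simulate_expression(bench14, m=50, seed=3)


@pytest.fixture(scope="session")
def printed_L5() -> np.ndarray:
    """The 5-node community matrix of the worked example: blocks {1,2,3}, {4,5}."""
    L = np.zeros((5, 5))
    L[:3, :3] = 1.0
    L[3:, 3:] = 1.0
    return L


def cloud_weight_matrix(n: int, seed: int, p0: float = 0.684) -> np.ndarray:
    """Pairwise (distance/p0)^2 weights of a clustered planar point cloud."""
    rng = np.random.default_rng(seed)
    centers = np.array([[0.0, 0.0], [2.0, 2.0], [-1.5, 2.5]])
    pts = np.vstack(
        [
            rng.normal(loc=centers[k % 3], scale=0.3, size=(1, 2))
            for k in range(n)
        ]
    )
    D = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=-1)
    W1 = (D / p0) ** 2
    np.fill_diagonal(W1, 0.0)
    return W1
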