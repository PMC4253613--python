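import numpy as np
import pytest

from tbest.datasets import gen_noise_matrix
from tbest.tree import Dendrogram, grow_tree


@pytest.fixture
def four_leaf_tree() -> Dendrogram:
    """Single linkage on the 1-D points {0, 1, 10, 11}: heights 1, 1, 9."""
    Z = np.array(
        [
            [0.0, 1.0, 1.0, 2.0],
            [2.0, 3.0, 1.0, 2.0],
            [4.0, 5.0, 9.0, 4.0],
        ]
    )
    return Dendrogram(Z)


@pytest.fixture
def balanced_eight_tree() -> Dendrogram:
    """Balanced 8-leaf tree: four tight pairs, two mid nodes, one root."""
    Z = np.array(
        [
            [0, 1, 1.0, 2],
            [2, 3, 1.0, 2],
            [4, 5, 1.0, 2],
            [6, 7, 1.0, 2],
            [8, 9, 2.0, 4],
            [10, 11, 2.0, 4],
            [12, 13, 4.0, 8],
        ],
        dtype=float,
    )
    return Dendrogram(Z)


def random_tree(seed: int, n_obs: int = 12, n_vars: int = 6, metric: str = "euclidean",
                linkage: str = "average") -> Dendrogram:
    X = gen_noise_matrix(n_obs, n_vars, seed=seed)
    return grow_tree(X.to_numpy(), metric=metric, linkage=linkage)
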