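import numpy as np
import pytest

from tabimg import (
    DistanceSpec,
    ImageGrid,
    TabularDataset,
    feature_distance_rank_matrix,
    pixel_distance_rank_matrix,
)


def random_table(n_samples, n_features, seed):
    rng = np.random.default_rng(seed)
    return TabularDataset(rng.standard_normal((n_samples, n_features)))


def random_rank_pair(n_features, seed, grid=None, ties="average"):
    """A feature rank matrix from random data plus a pixel rank matrix."""
    if grid is None:
        grid = ImageGrid(1, n_features)
    assert grid.size == n_features
    spec = DistanceSpec(ties=ties)
    data = random_table(max(4, n_features // 2), n_features, seed)
    R = feature_distance_rank_matrix(data, spec)
    Q = pixel_distance_rank_matrix(grid, spec)
    return R.ranks, Q.ranks


def swap_rows_cols(matrix, a, b):
    out = matrix.copy()
    out[[a, b], :] = out[[b, a], :]
    out[:, [a, b]] = out[:, [b, a]]
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
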