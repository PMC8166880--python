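"""Rank-matrix construction: distances, ascending ranks, tie averaging."""

import numpy as np
import pytest

from tabimg import (
    DistanceSpec,
    ImageGrid,
    TabularDataset,
    feature_distance_rank_matrix,
    pad_or_trim_to_grid,
    pixel_coordinates,
    pixel_distance_rank_matrix,
    select_top_variance_features,
)

from conftest import random_table


class TestTopVarianceSelection:
    def test_keeps_highest_variance_in_original_order(self):
        values = np.array([[0.0, 0.0, 0.0], [0.0, 2.0, 1.0], [0.0, 4.0, 2.0]])
        data = TabularDataset(values, feature_names=["a", "b", "c"])
        out = select_top_variance_features(data, 2)
        assert out.feature_names == ["b", "c"]
        assert out.sample_ids == data.sample_ids

    def test_k_equal_n_is_identity(self):
        data = random_table(10, 6, seed=0)
        out = select_top_variance_features(data, 6)
        assert out.feature_names == data.feature_names
        np.testing.assert_array_equal(out.values, data.values)

    def test_matches_independent_variance_sort(self):
        data = random_table(100, 50, seed=1)
        out = select_top_variance_features(data, 25)
        # independent oracle: plain sort of per-column variances
        variances = [(np.var(data.values[:, j]), j) for j in range(50)]
        expected = {data.feature_names[j] for _, j in
                    sorted(variances, key=lambda t: -t[0])[:25]}
        assert set(out.feature_names) == expected
        # original relative order preserved
        positions = [data.feature_names.index(f) for f in out.feature_names]
        assert positions == sorted(positions)

    def test_k_too_large_raises(self):
        with pytest.raises(ValueError, match="exceeds"):
            select_top_variance_features(random_table(5, 4, seed=2), 5)


class TestPadOrTrim:
    def test_pads_with_zero_pseudo_features(self):
        data = random_table(5, 8, seed=3)
        out = pad_or_trim_to_grid(data, ImageGrid(3, 3))
        assert out.n_features == 9
        np.testing.assert_array_equal(out.values[:, 8], 0.0)
        np.testing.assert_array_equal(out.values[:, :8], data.values)

    def test_exact_fit_unchanged(self):
        data = random_table(5, 9, seed=4)
        out = pad_or_trim_to_grid(data, ImageGrid(3, 3))
        assert out is data

    def test_trim_keeps_top_variance(self):
        data = random_table(30, 12, seed=5)
        out = pad_or_trim_to_grid(data, ImageGrid(3, 3), allow_trim=True)
        expected = select_top_variance_features(data, 9)
        assert out.feature_names == expected.feature_names

    def test_oversize_without_permission_raises(self):
        with pytest.raises(ValueError, match="allow_trim"):
            pad_or_trim_to_grid(random_table(5, 12, seed=6), ImageGrid(3, 3))


class TestFeatureRankMatrix:
    def test_hand_computed_euclidean_example(self):
        # columns (0,0), (1,1), (3,3): d12=sqrt2 < d23=2*sqrt2 < d13=3*sqrt2
        data = TabularDataset(np.array([[0.0, 1.0, 3.0], [0.0, 1.0, 3.0]]))
        R = feature_distance_rank_matrix(data).ranks
        assert R[1, 0] == 1 and R[2, 0] == 3 and R[2, 1] == 2

    @pytest.mark.parametrize("ties", ["average", "ordinal"])
    def test_symmetry_zero_diagonal_and_rank_sum(self, ties):
        data = random_table(9, 12, seed=7)
        R = feature_distance_rank_matrix(data, DistanceSpec(ties=ties)).ranks
        np.testing.assert_array_equal(R, R.T)
        np.testing.assert_array_equal(np.diag(R), 0.0)
        k = 12 * 11 // 2
        assert R[np.tril_indices(12, -1)].sum() == k * (k + 1) / 2

    def test_permutation_equivariance(self, rng):
        data = random_table(10, 8, seed=8)
        perm = rng.permutation(8)
        permuted = data.select_features(perm)
        R = feature_distance_rank_matrix(data).ranks
        R_perm = feature_distance_rank_matrix(permuted).ranks
        np.testing.assert_array_equal(R_perm, R[np.ix_(perm, perm)])

    def test_duplicated_features_share_smallest_rank(self):
        values = np.column_stack([np.arange(6.0), np.arange(6.0),
                                  np.arange(6.0) ** 2, np.ones(6)])
        data = TabularDataset(values)
        R = feature_distance_rank_matrix(data).ranks
        off_diag = R[np.tril_indices(4, -1)]
        assert R[1, 0] == off_diag.min()

    def test_constant_feature_under_correlation_raises(self):
        values = np.column_stack([np.arange(5.0), np.full(5, 3.0), np.arange(5.0) ** 2])
        data = TabularDataset(values, feature_names=["x", "const", "y"])
        with pytest.raises(ValueError, match="const"):
            feature_distance_rank_matrix(data, DistanceSpec(feature_metric="one_minus_correlation"))

    def test_jaccard_requires_binary(self):
        data = random_table(6, 4, seed=9)
        with pytest.raises(ValueError, match="binary"):
            feature_distance_rank_matrix(data, DistanceSpec(feature_metric="one_minus_jaccard"))

    def test_jaccard_on_binary_table(self):
        rng = np.random.default_rng(10)
        data = TabularDataset((rng.uniform(size=(12, 5)) > 0.5).astype(float))
        R = feature_distance_rank_matrix(data, DistanceSpec(feature_metric="one_minus_jaccard")).ranks
        np.testing.assert_array_equal(R, R.T)
        k = 5 * 4 // 2
        assert R[np.tril_indices(5, -1)].sum() == k * (k + 1) / 2


class TestPixelRankMatrix:
    def test_2x2_grid_tie_averaging(self):
        # four side pairs at distance 1 -> average rank (1+2+3+4)/4 = 2.5
        # two diagonal pairs at sqrt(2) -> average rank (5+6)/2 = 5.5
        Q = pixel_distance_rank_matrix(ImageGrid(2, 2)).ranks
        lower = Q[np.tril_indices(4, -1)]
        assert sorted(lower) == [2.5, 2.5, 2.5, 2.5, 5.5, 5.5]
        assert Q[1, 0] == 2.5 and Q[2, 0] == 2.5 and Q[3, 0] == 5.5

    def test_1x2_grid_single_pair(self):
        Q = pixel_distance_rank_matrix(ImageGrid(1, 2)).ranks
        np.testing.assert_array_equal(Q, [[0, 1], [1, 0]])

    def test_row_major_coordinates(self):
        coords = pixel_coordinates(ImageGrid(2, 3))
        np.testing.assert_array_equal(
            coords, [[0, 0], [0, 1], [0, 2], [1, 0], [1, 1], [1, 2]]
        )

    def test_transpose_grid_equivalence(self):
        # transposing the grid relabels pixels; Q follows that permutation
        nr, nc = 3, 4
        Q = pixel_distance_rank_matrix(ImageGrid(nr, nc)).ranks
        Qt = pixel_distance_rank_matrix(ImageGrid(nc, nr)).ranks
        idx = np.arange(nr * nc)
        perm = (idx % nc) * nr + idx // nc  # (r,c) -> position of (c,r) in transposed grid
        np.testing.assert_array_equal(Q, Qt[np.ix_(perm, perm)])

    def test_manhattan_metric_differs_from_euclidean(self):
        spec = DistanceSpec(pixel_metric="manhattan")
        Qm = pixel_distance_rank_matrix(ImageGrid(3, 3), spec).ranks
        Qe = pixel_distance_rank_matrix(ImageGrid(3, 3)).ranks
        assert not np.array_equal(Qm, Qe)
        k = 9 * 8 // 2
        assert Qm[np.tril_indices(9, -1)].sum() == k * (k + 1) / 2

    def test_near_diagonal_ranks_are_small_on_50x50(self):
        # neighboring pixels (adjacent linear indices) have small distances,
        # so the band near the matrix diagonal holds below-median ranks
        Q = pixel_distance_rank_matrix(ImageGrid(50, 50)).ranks
        n = 2500
        median_rank = (n * (n - 1) / 2 + 1) / 2
        near = np.array([Q[i + 1, i] for i in range(n - 1) if (i + 1) % 50 != 0])
        assert near.mean() < median_rank / 4
        assert np.all(near < median_rank)
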