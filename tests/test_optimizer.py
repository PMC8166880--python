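"""Swap optimizer: error function, incremental deltas, search dynamics."""

import itertools

import numpy as np
import pytest

from tabimg import (
    DistanceSpec,
    IGTDConfig,
    ImageGrid,
    apply_ordering,
    best_swap_for,
    err,
    generate_planted_layout_instance,
    igtd_optimize,
    pixel_distance_rank_matrix,
    swap_error_delta,
)

from conftest import random_rank_pair, swap_rows_cols


def lower_triangle_matrix(values):
    """Build a symmetric zero-diagonal 3x3 matrix from (m21, m31, m32)."""
    m21, m31, m32 = values
    return np.array([[0, m21, m31], [m21, 0, m32], [m31, m32, 0]], dtype=float)


class TestErr:
    def test_identical_matrices_give_zero(self):
        R, Q = random_rank_pair(6, seed=0)
        assert err(R, R) == 0.0
        assert err(Q, Q, "squared") == 0.0

    @pytest.mark.parametrize("diff_fn,expected", [("absolute", 4.0), ("squared", 6.0)])
    def test_three_feature_example(self, diff_fn, expected):
        R = lower_triangle_matrix((1, 2, 3))
        Q = lower_triangle_matrix((2, 3, 1))
        assert err(R, Q, diff_fn) == expected

    def test_shape_mismatch_raises(self):
        R, _ = random_rank_pair(4, seed=1)
        _, Q = random_rank_pair(5, seed=1)
        with pytest.raises(ValueError, match="mismatch"):
            err(R, Q)


class TestSwapErrorDelta:
    @pytest.mark.parametrize("diff_fn", ["absolute", "squared"])
    def test_equals_full_recomputation(self, diff_fn, rng):
        for _ in range(200):
            n = int(rng.integers(4, 13))
            R, Q = random_rank_pair(n, seed=int(rng.integers(1 << 30)))
            a, b = rng.choice(n, size=2, replace=False)
            delta = swap_error_delta(R, Q, int(a), int(b), diff_fn)
            full = err(R, Q, diff_fn) - err(swap_rows_cols(R, a, b), Q, diff_fn)
            assert delta == pytest.approx(full, abs=1e-9)

    def test_symmetric_in_the_pair(self):
        R, Q = random_rank_pair(7, seed=2)
        assert swap_error_delta(R, Q, 1, 5) == swap_error_delta(R, Q, 5, 1)

    def test_duplicated_features_have_zero_delta(self):
        values = np.column_stack([np.arange(6.0), np.arange(6.0), np.arange(6.0) ** 2,
                                  np.cos(np.arange(6.0))])
        from tabimg import TabularDataset, feature_distance_rank_matrix
        R = feature_distance_rank_matrix(TabularDataset(values)).ranks
        Q = pixel_distance_rank_matrix(ImageGrid(2, 2)).ranks
        assert swap_error_delta(R, Q, 0, 1) == 0.0

    def test_self_swap_raises(self):
        R, Q = random_rank_pair(4, seed=3)
        with pytest.raises(ValueError):
            swap_error_delta(R, Q, 2, 2)


class TestBestSwap:
    def test_two_features_single_candidate(self):
        R, Q = random_rank_pair(2, seed=4)
        l_star, _ = best_swap_for(R, Q, 0)
        assert l_star == 1

    def test_matches_exhaustive_scan(self, rng):
        for seed in range(10):
            R, Q = random_rank_pair(8, seed=seed)
            n_star = int(rng.integers(8))
            l_star, delta = best_swap_for(R, Q, n_star)
            candidates = [(swap_error_delta(R, Q, n_star, l), l)
                          for l in range(8) if l != n_star]
            best_delta = max(d for d, _ in candidates)
            best_l = min(l for d, l in candidates if d == best_delta)
            assert delta == pytest.approx(best_delta, abs=1e-9)
            assert l_star == best_l

    def test_all_equal_deltas_pick_smallest_index(self):
        # fully tied rank matrices: every swap leaves the error unchanged
        R = lower_triangle_matrix((2, 2, 2))
        Q = lower_triangle_matrix((2, 2, 2))
        l_star, delta = best_swap_for(R, Q, 1)
        assert (l_star, delta) == (0, 0.0)


class TestOptimize:
    def test_monotone_trace_with_nonnegative_t_swap(self):
        for seed in range(5):
            R, Q = random_rank_pair(16, seed=seed, grid=ImageGrid(4, 4))
            res = igtd_optimize(R, Q, IGTDConfig(s_max=1000, s_con=100))
            assert np.all(np.diff(res.error_trace) <= 0)

    @pytest.mark.parametrize("shape", [(2, 2), (2, 3)])
    def test_planted_small_2d_grids_reach_zero(self, shape):
        grid = ImageGrid(*shape)
        Q = pixel_distance_rank_matrix(grid)
        for seed in range(30):
            R, truth = generate_planted_layout_instance(grid, seed=seed)
            res = igtd_optimize(R, Q, IGTDConfig(s_max=1000, s_con=100))
            assert res.error == 0.0
            # layout recovered up to an automorphism of the grid
            assert err(apply_ordering(R, res.ordering), Q) == 0.0

    def test_planted_inverse_truth_is_optimal(self):
        grid = ImageGrid(3, 3)
        Q = pixel_distance_rank_matrix(grid)
        R, truth = generate_planted_layout_instance(grid, seed=11)
        inverse = np.argsort(truth)
        assert err(apply_ordering(R, inverse), Q) == 0.0

    def test_final_error_bounded_by_exhaustive_minimum(self):
        grid = ImageGrid(2, 3)
        Q = pixel_distance_rank_matrix(grid).ranks
        for seed in range(5):
            R, _ = random_rank_pair(6, seed=seed, grid=grid)
            res = igtd_optimize(R, Q, IGTDConfig(s_max=1000, s_con=100))
            brute = min(err(R[np.ix_(p, p)], Q)
                        for p in itertools.permutations(range(6)))
            assert brute <= res.error <= res.error_trace[0]
            assert res.error == err(apply_ordering(R, res.ordering), Q)

    def test_round_robin_fairness(self):
        # between two considerations of the same candidate, every other
        # feature must have been considered (as candidate or swap partner)
        R, Q = random_rank_pair(12, seed=7, grid=ImageGrid(3, 4))
        res = igtd_optimize(R, Q, IGTDConfig(s_max=400, s_con=100))
        last_pick = {}
        last_seen = {f: -1 for f in range(12)}
        for s, (n_star, l_star, accepted) in enumerate(res.moves):
            if n_star in last_pick:
                for other in range(12):
                    if other != n_star:
                        assert last_seen[other] >= last_pick[n_star]
            last_pick[n_star] = s
            last_seen[n_star] = s
            if accepted:
                last_seen[l_star] = s

    def test_negative_t_swap_returns_trace_minimum(self):
        R, Q = random_rank_pair(9, seed=8, grid=ImageGrid(3, 3))
        res = igtd_optimize(R, Q, IGTDConfig(s_max=600, s_con=100, t_swap=-0.05))
        assert np.any(np.diff(res.error_trace) > 0)  # uphill moves happened
        assert res.error == res.error_trace.min()
        assert res.error == err(apply_ordering(R, res.ordering), Q)
        assert res.error_trace[res.best_iteration] == res.error

    def test_zero_initial_error_returns_identity(self):
        Q = pixel_distance_rank_matrix(ImageGrid(2, 3))
        res = igtd_optimize(Q, Q, IGTDConfig(s_max=100, s_con=10))
        assert res.error == 0.0 and res.n_iterations == 0 and res.converged
        np.testing.assert_array_equal(res.ordering, np.arange(6))

    def test_every_intermediate_ordering_is_a_permutation(self):
        R, Q = random_rank_pair(8, seed=9, grid=ImageGrid(2, 4))
        res = igtd_optimize(R, Q, IGTDConfig(s_max=200, s_con=50))
        ordering = np.arange(8)
        for a, b, accepted in res.moves:
            if accepted:
                ordering[a], ordering[b] = ordering[b], ordering[a]
            assert sorted(ordering) == list(range(8))

    def test_terminates_by_s_max(self):
        R, Q = random_rank_pair(25, seed=10, grid=ImageGrid(5, 5))
        res = igtd_optimize(R, Q, IGTDConfig(s_max=50, s_con=25))
        assert res.n_iterations <= 50
        if not res.converged:
            assert res.n_iterations == 50


class TestApplyOrdering:
    def test_identity_and_inverse_round_trip(self, rng):
        R, _ = random_rank_pair(7, seed=11)
        np.testing.assert_array_equal(apply_ordering(R, np.arange(7)).ranks, R)
        perm = rng.permutation(7)
        back = apply_ordering(apply_ordering(R, perm), np.argsort(perm))
        np.testing.assert_array_equal(back.ranks, R)

    def test_rejects_non_permutation(self):
        R, _ = random_rank_pair(5, seed=12)
        with pytest.raises(ValueError, match="permutation"):
            apply_ordering(R, np.array([0, 1, 1, 3, 4]))
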