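"""NCA weighting and the iterative top-k (INCA) loop.

Oracles: central finite differences for the gradient; exhaustive per-k
cross-validation with the standalone 1-NN predictor for the loss curve.
"""

import numpy as np
import pytest

from pdfe import (
    ConfigurationError,
    NCAConfig,
    ValidationError,
    inca_select,
    make_planted_features,
    nca_weights,
)
from pdfe.selection import _standardize, nca_objective_grad, rank_features


def _finite_diff_grad(Xs, y, w, sigma, lam, eps=1e-6):
    fd = np.zeros_like(w)
    for r in range(len(w)):
        wp, wm = w.copy(), w.copy()
        wp[r] += eps
        wm[r] -= eps
        op, _ = nca_objective_grad(Xs, y, wp, sigma, lam)
        om, _ = nca_objective_grad(Xs, y, wm, sigma, lam)
        fd[r] = (op - om) / (2 * eps)
    return fd


class TestNCAWeights:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_gradient_matches_finite_differences(self, seed):
        """Analytic gradient vs central differences, 8 samples x 5 features."""
        rng = np.random.default_rng(seed)
        Xs = _standardize(rng.standard_normal((8, 5)))
        y = rng.permutation(np.array([0, 0, 0, 0, 1, 1, 1, 1]))
        w = np.ones(5) if seed % 2 == 0 else rng.uniform(0.2, 2.0, size=5)
        obj, grad = nca_objective_grad(Xs, y, w, sigma=1.0, lam=1 / 8)
        fd = _finite_diff_grad(Xs, y, w, sigma=1.0, lam=1 / 8)
        assert np.abs(grad - fd).max() <= 1e-4 * max(1.0, np.abs(fd).max())

    def test_separating_feature_gets_max_weight(self):
        """One perfectly separating feature among 9 pure-noise features."""
        rng = np.random.default_rng(7)
        n = 40
        y = np.repeat([0, 1], n // 2)
        X = rng.standard_normal((n, 10))
        X[:, 4] = np.where(y == 0, -3.0, 3.0) + 0.1 * rng.standard_normal(n)
        w = nca_weights(X, y, NCAConfig(max_iters=60))
        assert w.weights.argmax() == 4

    def test_objective_trace_non_decreasing(self):
        X, y, _ = make_planted_features(30, 2, 8, effect=1.0, seed=3)
        w = nca_weights(X, y, NCAConfig(max_iters=40))
        trace = w.objective_trace
        assert all(b >= a for a, b in zip(trace, trace[1:]))

    def test_shrinkage_dominates_on_permuted_labels(self):
        """Signal destroyed + heavy penalty: weights fall below the all-ones
        initialization."""
        rng = np.random.default_rng(11)
        X, y, _ = make_planted_features(40, 3, 7, effect=2.0, seed=11)
        y_perm = rng.permutation(y)
        w = nca_weights(X, y_perm, NCAConfig(max_iters=80, lambda_reg=5.0))
        assert w.weights.max() < 1.0

    def test_weights_nonnegative_and_finite(self):
        X, y, _ = make_planted_features(24, 2, 10, effect=1.0, seed=5)
        w = nca_weights(X, y, NCAConfig(max_iters=30))
        assert np.all(w.weights >= 0)
        assert np.all(np.isfinite(w.weights))

    def test_single_class_rejected(self):
        X = np.random.default_rng(0).standard_normal((10, 3))
        with pytest.raises(ValidationError):
            nca_weights(X, np.zeros(10, dtype=int), NCAConfig())

    def test_zero_variance_column_keeps_shrunk_initial_weight(self):
        X, y, _ = make_planted_features(30, 2, 5, effect=1.5, seed=9)
        X[:, 0] = 3.14  # constant column: no pairwise contribution
        w = nca_weights(X, y, NCAConfig(max_iters=30))
        # only the penalty acts on it, so it can never exceed the start value
        assert w.weights[0] <= 1.0
        assert w.weights.argmax() != 0

    def test_backend_agreement_jit_vs_numpy(self):
        """Blocked JIT kernels and the NumPy fallback agree to roundoff."""
        import pdfe.selection as sel

        if not sel._HAVE_NUMBA:
            X, y, _ = make_planted_features(20, 2, 6, effect=1.0, seed=2)
            nca_weights(X, y, NCAConfig(max_iters=5))  # fallback-only env
            return
        rng = np.random.default_rng(4)
        X = rng.standard_normal((20, 37))
        iu, ju = np.triu_indices(20, 1)
        w2 = rng.uniform(size=37)
        m = rng.standard_normal(iu.size)
        d_jit = sel._pair_dist(X, iu, ju, w2)
        g_jit = sel._pair_weighted_sum(X, iu, ju, m)
        sel._HAVE_NUMBA = False
        try:
            d_np = sel._pair_dist(X, iu, ju, w2)
            g_np = sel._pair_weighted_sum(X, iu, ju, m)
        finally:
            sel._HAVE_NUMBA = True
        assert np.allclose(d_jit, d_np, rtol=1e-9, atol=1e-12)
        assert np.allclose(g_jit, g_np, rtol=1e-9, atol=1e-12)


from oracles import brute_force_prefix_losses as _brute_force_prefix_losses  # noqa: E402


class TestINCALoop:
    def test_loss_curve_matches_brute_force_oracle(self):
        """Per-k losses equal an exhaustive independent recomputation."""
        X, y, _ = make_planted_features(40, 3, 9, effect=1.2, seed=21)
        w = nca_weights(X, y, NCAConfig(max_iters=25))
        res = inca_select(X, y, w, k_min=1, k_max=12, loss_folds=10, seed=5)
        oracle = _brute_force_prefix_losses(
            X.astype(np.float64), y, res.ranked_indices, res.ks, 10, 5
        )
        assert np.array_equal(res.losses, oracle)
        assert res.losses[res.chosen_k - res.k_min] == res.losses.min()
        first_min = res.ks[np.flatnonzero(res.losses == res.losses.min())[0]]
        assert res.chosen_k == first_min  # smallest-k tie-break

    def test_perfect_single_feature_chooses_k1(self):
        rng = np.random.default_rng(2)
        n = 40
        y = np.repeat([0, 1], n // 2)
        X = rng.standard_normal((n, 8))
        X[:, 0] = np.where(y == 0, -5.0, 5.0)
        weights = np.array([10.0, 1, 1, 1, 1, 1, 1, 1])
        res = inca_select(X, y, weights, k_min=1, k_max=8, loss_folds=10, seed=0)
        assert res.chosen_k == 1
        assert res.losses[0] == 0.0
        assert list(res.selected_indices) == [0]

    def test_rank_ties_break_to_lower_index(self):
        w = np.array([0.5, 0.9, 0.5, 0.9])
        assert list(rank_features(w)) == [1, 3, 0, 2]

    def test_selected_indices_are_unique_prefix(self):
        X, y, _ = make_planted_features(30, 2, 10, effect=1.0, seed=8)
        w = nca_weights(X, y, NCAConfig(max_iters=15))
        res = inca_select(X, y, w, k_max=12, loss_folds=10, seed=1)
        assert len(set(res.selected_indices.tolist())) == res.chosen_k
        assert np.array_equal(res.selected_indices, res.ranked_indices[: res.chosen_k])

    def test_determinism(self):
        X, y, _ = make_planted_features(30, 2, 10, effect=1.0, seed=13)
        w1 = nca_weights(X, y, NCAConfig(max_iters=20))
        w2 = nca_weights(X, y, NCAConfig(max_iters=20))
        assert np.array_equal(w1.weights, w2.weights)
        r1 = inca_select(X, y, w1, k_max=12, loss_folds=10, seed=3)
        r2 = inca_select(X, y, w2, k_max=12, loss_folds=10, seed=3)
        assert np.array_equal(r1.losses, r2.losses)
        assert r1.chosen_k == r2.chosen_k

    def test_too_few_samples_for_folds_suggests_fewer(self):
        X, y, _ = make_planted_features(8, 1, 3, effect=1.0, seed=0)
        with pytest.raises(ValidationError, match="fewer folds"):
            inca_select(X, y, np.ones(4), loss_folds=10, seed=0)

    def test_invalid_loop_bounds_rejected(self):
        X, y, _ = make_planted_features(20, 1, 3, effect=1.0, seed=0)
        with pytest.raises(ConfigurationError):
            inca_select(X, y, np.ones(4), k_min=5, k_max=2, loss_folds=5, seed=0)


def test_planted_feature_recovery_statistics():
    """5 exchangeable informative features among 95 noise (n=100, moderate
    effect): the selector ranks the planted signal near the top and keeps
    almost all of it. Because the planted columns are mutually redundant,
    the smallest-k tie-break may legitimately stop before the last one, so
    the guarantees are: every replicate selects at least 4 of 5, and nearly
    all replicates rank all 5 within the top 10."""
    n_rep = 20
    at_least_4 = 0
    all_in_top10 = 0
    for seed in range(n_rep):
        X, y, planted = make_planted_features(
            n_samples=100, n_informative=5, n_noise=95, effect=1.5, seed=seed
        )
        w = nca_weights(X, y, NCAConfig())
        res = inca_select(X, y, w, k_min=1, k_max=100, loss_folds=10, seed=seed)
        selected = set(res.selected_indices.tolist())
        at_least_4 += len(selected & set(planted.tolist())) >= 4
        ranks = np.flatnonzero(np.isin(res.ranked_indices, planted))
        all_in_top10 += ranks.max() < 10
    assert at_least_4 == n_rep
    assert all_in_top10 >= 0.85 * n_rep
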