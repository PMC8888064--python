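import numpy as np
import pytest

from hemolyzer import elm


def gaussian_blobs(n_per_class=100, P=10, sep=6.0, noise=1.0, seed=0):
    """Well-separated 3-class Gaussian features with labels."""
    rng = np.random.default_rng(seed)
    centers = rng.standard_normal((3, P)) * sep
    X = np.vstack([centers[c] + noise * rng.standard_normal((n_per_class, P)) for c in range(3)])
    y = np.repeat(np.arange(3), n_per_class)
    return X, y


class TestOneHot:
    def test_examples(self):
        assert np.array_equal(elm.one_hot(1, 3), [0, 1, 0])
        assert np.array_equal(elm.one_hot(0, 3), [1, 0, 0])

    def test_round_trip(self):
        for c in range(3):
            assert np.argmax(elm.one_hot(c, 3)) == c

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            elm.one_hot(3, 3)


class TestInitHidden:
    def test_deterministic(self):
        a = elm.init_hidden(4, 10, seed=7)
        b = elm.init_hidden(4, 10, seed=7)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    def test_shapes_and_range(self):
        W, b = elm.init_hidden(4, 10, seed=1)
        assert W.shape == (10, 4) and b.shape == (10,)
        assert np.all(np.abs(W) <= 1) and np.all(np.abs(b) <= 1)

    def test_invalid_dims_rejected(self):
        with pytest.raises(ValueError):
            elm.init_hidden(0, 5, seed=0)


class TestMapFeatures:
    def test_sigmoid_at_zero(self):
        H = elm.map_features(np.zeros((1, 3)), np.zeros((2, 3)), np.zeros(2))
        assert np.allclose(H, 0.5)

    def test_saturation_at_large_bias(self):
        H = elm.map_features(np.zeros((1, 2)), np.zeros((4, 2)), np.full(4, 20.0))
        assert np.all(H > 0.999)

    def test_matches_per_element_loop(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((5, 3))
        W = rng.uniform(-1, 1, (4, 3))
        b = rng.uniform(-1, 1, 4)
        H = elm.map_features(X, W, b)
        for n in range(5):
            for i in range(4):
                z = X[n] @ W[i] + b[i]
                assert H[n, i] == pytest.approx(1 / (1 + np.exp(-z)), abs=1e-12)

    def test_outputs_in_open_unit_interval(self):
        rng = np.random.default_rng(4)
        H = elm.map_features(rng.standard_normal((10, 5)), *elm.init_hidden(5, 8, 1))
        assert np.all(H > 0) and np.all(H < 1)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            elm.map_features(np.array([[np.inf]]), np.ones((1, 1)), np.zeros(1))


class TestSolvers:
    def test_identity_system(self):
        T = np.array([[1.0, 0.0], [0.0, 1.0]])
        assert np.allclose(elm.solve_beta_pinv(np.eye(2), T), T)

    def test_invertible_square_system(self):
        rng = np.random.default_rng(5)
        H = rng.standard_normal((4, 4)) + 4 * np.eye(4)
        T = rng.standard_normal((4, 3))
        assert np.allclose(elm.solve_beta_pinv(H, T), np.linalg.solve(H, T), atol=1e-9)

    def test_pinv_beats_random_candidates(self):
        rng = np.random.default_rng(6)
        H = rng.standard_normal((40, 10))
        T = rng.standard_normal((40, 3))
        beta = elm.solve_beta_pinv(H, T)
        best = np.linalg.norm(H @ beta - T)
        for _ in range(1000):
            cand = beta + rng.standard_normal(beta.shape) * rng.uniform(0.01, 1)
            assert np.linalg.norm(H @ cand - T) >= best - 1e-12

    def test_ridge_zero_alpha_matches_pinv(self):
        rng = np.random.default_rng(7)
        H = rng.standard_normal((30, 8))  # full column rank a.s.
        T = rng.standard_normal((30, 3))
        assert np.allclose(
            elm.solve_beta_ridge(H, T, 0.0), elm.solve_beta_pinv(H, T), atol=1e-8
        )

    def test_ridge_shrinks_to_zero(self):
        rng = np.random.default_rng(8)
        H = rng.standard_normal((30, 8))
        T = rng.standard_normal((30, 3))
        big = elm.solve_beta_ridge(H, T, 1e6)
        ref = elm.solve_beta_pinv(H, T)
        assert np.linalg.norm(big) < 1e-3 * np.linalg.norm(ref)

    @pytest.mark.parametrize("seed", range(3))
    def test_ridge_satisfies_normal_equations(self, seed):
        rng = np.random.default_rng(seed)
        H = rng.standard_normal((25, 12))
        T = rng.standard_normal((25, 3))
        alpha = 0.37
        beta = elm.solve_beta_ridge(H, T, alpha)
        lhs = (H.T @ H + alpha * np.eye(12)) @ beta
        rhs = H.T @ T
        assert np.linalg.norm(lhs - rhs) <= 1e-8 * np.linalg.norm(rhs)

    def test_negative_alpha_rejected(self):
        with pytest.raises(ValueError):
            elm.solve_beta_ridge(np.eye(2), np.eye(2), -0.1)


class TestPredict:
    def test_recovers_training_labels_on_separable_blobs(self):
        X, y = gaussian_blobs(seed=1)
        model = elm.fit(X, y, hidden_nodes=100, alpha=0.01, seed=2)
        assert np.mean(elm.predict(X, model) == y) == 1.0

    def test_row_order_permutes_predictions(self):
        X, y = gaussian_blobs(n_per_class=20, seed=3)
        model = elm.fit(X, y, hidden_nodes=50, seed=4)
        perm = np.random.default_rng(5).permutation(len(X))
        assert np.array_equal(elm.predict(X, model)[perm], elm.predict(X[perm], model))

    def test_untrained_model_rejected(self):
        W, b = elm.init_hidden(3, 5, 0)
        model = elm.ElmModel(W=W, b=b, alpha=0.0, beta=None, n_classes=3)
        with pytest.raises(ValueError):
            elm.predict(np.zeros((1, 3)), model)

    def test_holdout_recovery(self):
        X, y = gaussian_blobs(n_per_class=100, P=10, seed=11)
        rng = np.random.default_rng(12)
        idx = rng.permutation(len(X))
        tr, te = idx[:240], idx[240:]
        model = elm.fit(X[tr], y[tr], hidden_nodes=100, alpha=0.01, seed=13)
        assert np.mean(elm.predict(X[te], model) == y[te]) >= 0.98


class TestKfold:
    def test_equal_fold_sizes(self):
        folds = elm.kfold_indices(8, 4, seed=0)
        assert [len(f) for f in folds] == [2, 2, 2, 2]

    def test_partition_property(self):
        folds = elm.kfold_indices(23, 5, seed=1)
        allidx = np.concatenate(folds)
        assert sorted(allidx) == list(range(23))
        sizes = sorted(len(f) for f in folds)
        assert sizes[-1] - sizes[0] <= 1

    def test_reproducible(self):
        a = elm.kfold_indices(10, 3, seed=2)
        b = elm.kfold_indices(10, 3, seed=2)
        assert all(np.array_equal(x, y) for x, y in zip(a, b))

    def test_k_exceeding_n_rejected(self):
        with pytest.raises(ValueError):
            elm.kfold_indices(3, 5, seed=0)


class TestSweep:
    def test_single_candidate_table(self):
        X, y = gaussian_blobs(n_per_class=20, seed=6)
        table, best = elm.sweep_hidden_nodes(X, y, candidates=[10], k=4, seed=7)
        assert len(table) == 1 and best == 10

    def test_selected_is_member(self):
        X, y = gaussian_blobs(n_per_class=20, seed=8)
        table, best = elm.sweep_hidden_nodes(X, y, candidates=[10, 50], k=4, seed=9)
        assert best in (10, 50)

    def test_single_class_rejected(self):
        X = np.random.default_rng(0).standard_normal((20, 4))
        with pytest.raises(ValueError):
            elm.sweep_hidden_nodes(X, np.zeros(20, int), candidates=[10], k=4, seed=0)

    def test_select_alpha_returns_member(self):
        X, y = gaussian_blobs(n_per_class=20, seed=10)
        table, best = elm.select_alpha(X, y, hidden_nodes=50, candidates=(0.01, 1.0), k=4, seed=1)
        assert best in (0.01, 1.0)
        assert len(table) == 2
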