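"""Multi-kernel SVM core: kernels, mixing, dual solver, grid search."""
import numpy as np
import pytest

from brainmkl.diagnostics import active_set_dual, brute_force_dual
from brainmkl.exceptions import ConfigError, InputError
from brainmkl.mkl import (
    MKLResults, MultiKernelSVM, Standardizer, decision_value, dual_objective,
    grid_search, linear_kernel, mix_kernels, predict_label, simplex_grid,
    solve_dual, validate_simplex,
)


def _random_problem(seed, n=None, d=3, separation=0.0):
    r = np.random.default_rng(seed)
    n = n if n is not None else int(r.integers(3, 7))
    X = r.standard_normal((n, d))
    y = np.ones(n)
    y[: n // 2] = -1
    y = r.permutation(y)
    if abs(y.sum()) >= n:
        y[0] *= -1
    X[y == 1] += separation
    return X @ X.T, y


class TestSimplexGrid:
    @pytest.mark.parametrize("m,count", [(1, 1), (2, 11), (3, 66)])
    def test_lattice_counts(self, m, count):
        grid = simplex_grid(m, 0.1)
        assert grid.shape == (count, m)

    def test_rows_are_on_the_simplex(self):
        grid = simplex_grid(3, 0.1)
        assert np.all(grid >= 0)
        np.testing.assert_allclose(grid.sum(axis=1), 1.0, atol=1e-12)

    def test_step_must_divide_one(self):
        with pytest.raises(ConfigError):
            simplex_grid(2, 0.3)


class TestLinearKernel:
    def test_identity_features_without_standardization(self):
        K = linear_kernel(np.eye(2))
        np.testing.assert_allclose(K, np.eye(2))

    def test_dot_product_value(self):
        K = linear_kernel(np.array([[1.0, 2.0]]), np.array([[3.0, 4.0]]))
        assert K[0, 0] == pytest.approx(11.0)

    def test_self_kernel_is_symmetric_psd(self, rng):
        X = rng.standard_normal((8, 4))
        K = linear_kernel(X)
        np.testing.assert_allclose(K, K.T, atol=1e-12)
        assert np.linalg.eigvalsh(K).min() > -1e-9

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(InputError):
            linear_kernel(np.ones((2, 3)), np.ones((2, 4)))

    def test_standardizer_handles_constant_features(self):
        X = np.array([[1.0, 5.0], [1.0, 7.0]])
        s = Standardizer().fit(X)
        Z = s.transform(X)
        assert np.all(Z[:, 0] == 0.0)
        assert Z[:, 1].std() == pytest.approx(1.0)


class TestMixKernels:
    def test_vertex_weight_returns_that_kernel(self, rng):
        ks = [rng.standard_normal((3, 3)) for _ in range(3)]
        np.testing.assert_allclose(mix_kernels(ks, [1.0, 0.0, 0.0]), ks[0])

    def test_identical_kernels_any_weights(self, rng):
        k = rng.standard_normal((3, 3))
        np.testing.assert_allclose(mix_kernels([k, k, k], [0.2, 0.3, 0.5]), k, atol=1e-12)

    def test_scalar_mixture(self):
        out = mix_kernels([np.array([[2.0]]), np.array([[4.0]])], [0.5, 0.5])
        assert out[0, 0] == pytest.approx(3.0)

    def test_off_simplex_weights_rejected(self):
        with pytest.raises(InputError):
            mix_kernels([np.eye(2), np.eye(2)], [0.7, 0.7])

    def test_shape_mismatch_rejected(self):
        with pytest.raises(InputError):
            mix_kernels([np.eye(2), np.eye(3)], [0.5, 0.5])


class TestSolveDual:
    def test_two_point_closed_form(self):
        K = np.array([[1.0, -1.0], [-1.0, 1.0]])
        alpha, b = solve_dual(K, [1, -1], C=10.0)
        np.testing.assert_allclose(alpha, [0.5, 0.5], atol=1e-8)
        assert b == pytest.approx(0.0, abs=1e-8)

    def test_margin_condition_on_support_vector(self):
        K = np.array([[1.0, -1.0], [-1.0, 1.0]])
        alpha, b = solve_dual(K, [1, -1], C=10.0)
        f = decision_value(alpha, b, np.array([1.0, -1.0]), [K], [1.0])
        assert f[0] == pytest.approx(1.0, abs=1e-6)
        assert f[1] == pytest.approx(-1.0, abs=1e-6)

    def test_duplicated_dataset_leaves_decision_unchanged(self, rng):
        K, y = _random_problem(0, n=6, separation=1.0)
        X = rng.standard_normal((6, 3))
        K = X @ X.T
        Kt = rng.standard_normal((4, 3)) @ X.T
        a1, b1 = solve_dual(K, y, 1.0, tol=1e-10)
        f1 = Kt @ (a1 * y) + b1
        K2 = np.tile(K, (2, 2))
        y2 = np.concatenate([y, y])
        a2, b2 = solve_dual(K2, y2, 0.5, tol=1e-10)  # halve C to keep the optimum
        f2 = np.tile(Kt, (1, 2)) @ (a2 * y2) + b2
        np.testing.assert_allclose(f1, f2, atol=1e-6)

    @pytest.mark.parametrize("seed", range(6))
    def test_objective_matches_bruteforce_on_small_problems(self, seed):
        K, y = _random_problem(seed)
        alpha, _ = solve_dual(K, y, 1.0, tol=1e-9)
        obj = dual_objective(alpha, K, y)
        ref, _ = brute_force_dual(K, y, 1.0)
        assert obj == pytest.approx(ref, abs=1e-3)

    @pytest.mark.parametrize("seed", range(6))
    def test_bruteforce_grid_agrees_with_exact_enumeration(self, seed):
        """Validates the grid oracle itself against the exact concave-QP
        active-set enumeration."""
        K, y = _random_problem(seed + 50)
        grid_obj, _ = brute_force_dual(K, y, 1.0)
        exact_obj, _ = active_set_dual(K, y, 1.0)
        assert grid_obj == pytest.approx(exact_obj, abs=1e-4)

    def test_constraints_satisfied(self, rng):
        X = rng.standard_normal((20, 5))
        y = np.sign(rng.standard_normal(20))
        y[y == 0] = 1
        if abs(y.sum()) == 20:
            y[0] *= -1
        alpha, _ = solve_dual(X @ X.T, y, 1.0)
        assert np.all(alpha >= -1e-12) and np.all(alpha <= 1.0 + 1e-12)
        assert abs(alpha @ y) < 1e-8

    def test_single_class_rejected(self):
        with pytest.raises(InputError, match="both classes"):
            solve_dual(np.eye(3), [1, 1, 1], 1.0)

    def test_nonpositive_c_rejected(self):
        with pytest.raises(ConfigError):
            solve_dual(np.eye(2), [1, -1], 0.0)


class TestDecisionValue:
    def test_zero_alpha_gives_bias_everywhere(self):
        alpha = np.zeros(3)
        y = np.array([1.0, -1.0, 1.0])
        kt = [np.ones((5, 3))]
        f = decision_value(alpha, 0.7, y, kt, [1.0])
        np.testing.assert_allclose(f, 0.7)

    def test_tie_at_zero_predicts_positive(self):
        assert predict_label(np.array([0.0, -0.1, 0.1])).tolist() == [1, -1, 1]

    def test_vertex_beta_reduces_to_single_kernel(self, rng):
        Xs = [rng.standard_normal((10, 4)) for _ in range(3)]
        y = np.array([1.0] * 5 + [-1.0] * 5)
        ks = [X @ X.T for X in Xs]
        alpha, b = solve_dual(ks[1], y, 1.0, tol=1e-10)
        kt = [rng.standard_normal((6, 4)) @ X.T for X in Xs]
        f_mkl = decision_value(alpha, b, y, kt, [0.0, 1.0, 0.0])
        f_single = kt[1] @ (alpha * y) + b
        np.testing.assert_allclose(f_mkl, f_single, atol=1e-12)

    def test_mixing_is_linear_in_beta(self, rng):
        y = np.sign(rng.standard_normal(8))
        y[y == 0] = 1
        alpha = rng.uniform(0, 1, 8)
        kt = [rng.standard_normal((4, 8)) for _ in range(3)]
        beta = np.array([0.2, 0.5, 0.3])
        f = decision_value(alpha, 0.0, y, kt, beta)
        parts = [decision_value(alpha, 0.0, y, [k], [1.0]) for k in kt]
        np.testing.assert_allclose(f, sum(b * p for b, p in zip(beta, parts)), atol=1e-10)

    def test_modality_count_mismatch_rejected(self):
        with pytest.raises(InputError):
            decision_value(np.zeros(2), 0.0, np.array([1.0, -1.0]),
                           [np.ones((1, 2))], [0.5, 0.5])


class TestGridSearch:
    def test_single_modality_degenerates_to_unit_weight(self, rng):
        X = [rng.standard_normal((10, 3))]
        y = np.array([1.0] * 5 + [-1.0] * 5)
        beta, C, _ = grid_search(X, y)
        np.testing.assert_array_equal(beta, [1.0])
        assert C == 1.0

    def test_deterministic_given_seed(self, rng):
        Xs = [rng.standard_normal((20, 4)) for _ in range(2)]
        y = np.array([1.0] * 10 + [-1.0] * 10)
        out1 = grid_search(Xs, y, seed=3)
        out2 = grid_search(Xs, y, seed=3)
        np.testing.assert_array_equal(out1[0], out2[0])
        assert out1[1] == out2[1]

    def test_signal_modality_receives_largest_weight(self):
        """Only modality 0 separates the groups: its weight should dominate
        in the vast majority of random cohorts."""
        wins = 0
        n_seeds = 50
        for seed in range(n_seeds):
            r = np.random.default_rng(seed)
            n = 40
            y = np.concatenate([np.ones(20), -np.ones(20)])
            # signal: 5 shifted features; the other modalities carry only
            # high-dimensional noise, which hurts validation accuracy when
            # upweighted (as noise edges do in the real pipeline)
            Xs = [r.standard_normal((n, 5 if m == 0 else 40)) for m in range(3)]
            Xs[0][y == 1] += 1.2
            beta, _, _ = grid_search(Xs, y, seed=seed)
            wins += beta[0] >= max(beta[1], beta[2])
        assert wins / n_seeds >= 0.8

    def test_empty_c_grid_rejected(self, rng):
        X = [rng.standard_normal((8, 2)) for _ in range(2)]
        y = np.array([1.0] * 4 + [-1.0] * 4)
        with pytest.raises(ConfigError):
            grid_search(X, y, c_grid=())


class TestModelResults:
    def test_fit_satisfies_dual_feasibility_and_kkt(self, rng):
        Xs = [rng.standard_normal((24, 6)) for _ in range(3)]
        y = np.concatenate([np.ones(12), -np.ones(12)])
        Xs[0][y == 1] += 1.0
        model = MultiKernelSVM(y, Xs)
        res = model.fit(seed=0, tol=1e-8)
        assert res.dual_feasibility_gap < 1e-8
        assert np.all(res.alpha >= -1e-12) and np.all(res.alpha <= res.C + 1e-12)
        assert res.kkt_violation() < 1e-6

    def test_serialization_round_trip_preserves_predictions(self, rng, tmp_path):
        Xs = [rng.standard_normal((16, 4)) for _ in range(2)]
        y = np.concatenate([np.ones(8), -np.ones(8)])
        Xs[1][y == 1] += 0.8
        res = MultiKernelSVM(y, Xs).fit(seed=1)
        Xt = [rng.standard_normal((6, 4)) for _ in range(2)]
        res.to_json(tmp_path / "model.json")
        back = MKLResults.from_json(tmp_path / "model.json")
        np.testing.assert_allclose(
            res.decision_function(Xt), back.decision_function(Xt), atol=1e-12
        )

    def test_summary_mentions_weights_and_support_vectors(self, rng):
        Xs = [rng.standard_normal((10, 3))]
        y = np.array([1.0] * 5 + [-1.0] * 5)
        res = MultiKernelSVM(y, Xs).fit(beta=[1.0], C=1.0)
        text = res.summary()
        assert "kernel weights" in text and "support vectors" in text

    def test_validate_simplex_clips_tiny_negatives_only(self):
        with pytest.raises(InputError):
            validate_simplex([-0.2, 1.2])
        out = validate_simplex([1.0 + 1e-12, -1e-12])
        assert np.all(out >= 0)
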