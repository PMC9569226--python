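"""View-weighted L1 selection: objective, gradient, prox, ISTA, supports."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mvconn.selection import (SelectionModel, ViewPartition, encode_labels,
                              grad_f, ista_solve, lipschitz_estimate,
                              objective_f, objective_total, prox_step,
                              run_per_view_selection, select_support,
                              standardize_columns)
from mvconn.synth import SynthConfig, generate_multiview


def _objective_oracle(omega, X, y):
    """Summation-by-definition version of the smooth loss."""
    total = 0.0
    for i in range(X.shape[0]):
        r = y[i] - float(np.dot(omega, X[i]))
        total += r * r
    return total / (2 * X.shape[0])


class TestObjectiveAndGradient:
    def test_zero_cases(self):
        X = np.ones((4, 3))
        assert objective_f(np.zeros(3), X, np.zeros(4)) == 0.0
        w = np.array([1.0, -2.0, 0.5])
        assert objective_f(w, X, X @ w) == pytest.approx(0.0, abs=1e-15)

    def test_matches_loop_oracle(self, rng):
        X = rng.standard_normal((12, 5))
        y = rng.standard_normal(12)
        w = rng.standard_normal(5)
        assert objective_f(w, X, y) == pytest.approx(
            _objective_oracle(w, X, y), abs=1e-12)

    def test_gradient_zero_at_least_squares_solution(self, rng):
        X = rng.standard_normal((20, 6))
        y = rng.standard_normal(20)
        w_star, *_ = np.linalg.lstsq(X, y, rcond=None)
        assert np.max(np.abs(grad_f(w_star, X, y))) < 1e-9

    def test_gradient_matches_central_differences(self, rng):
        X = rng.standard_normal((10, 6))
        y = rng.standard_normal(10)
        w = rng.standard_normal(6)
        g = grad_f(w, X, y)
        h = 1e-6
        for p in range(6):
            e = np.zeros(6)
            e[p] = h
            fd = (objective_f(w + e, X, y) - objective_f(w - e, X, y)) / (2 * h)
            assert g[p] == pytest.approx(fd, abs=1e-4)

    def test_gradient_at_zero(self, rng):
        X = rng.standard_normal((8, 4))
        y = rng.standard_normal(8)
        assert np.allclose(grad_f(np.zeros(4), X, y), -X.T @ y / 8)

    def test_shape_errors(self):
        with pytest.raises(ValueError):
            objective_f(np.zeros(3), np.ones((4, 2)), np.zeros(4))
        with pytest.raises(ValueError):
            grad_f(np.zeros(2), np.ones((4, 2)), np.zeros(3))


class TestLipschitz:
    def test_identity_design(self):
        assert lipschitz_estimate(np.eye(7)) == pytest.approx(1 / 7)

    def test_single_column(self, rng):
        c = rng.standard_normal(9)
        X = np.zeros((9, 4))
        X[:, 2] = c
        assert lipschitz_estimate(X) == pytest.approx(float(c @ c) / 9)

    def test_matches_full_svd(self, rng):
        X = rng.standard_normal((20, 30))
        want = np.linalg.svd(X, compute_uv=False)[0] ** 2 / 20
        assert lipschitz_estimate(X) == pytest.approx(want, rel=1e-6)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            lipschitz_estimate(np.zeros((3, 3)))


class TestProxStep:
    def test_three_branches(self):
        a = np.ones(3)
        out = prox_step(np.array([0.5, 0.1, -0.5]), a, lam=0.2, L=1.0)
        assert np.allclose(out, [0.3, 0.0, -0.3])

    def test_threshold_monotonicity(self):
        """|prox(xi)| never grows when the threshold theta grows."""
        xi = np.linspace(-1, 1, 21)
        prev = None
        for theta in np.linspace(0.0, 1.0, 11):
            out = np.abs(prox_step(xi, np.ones_like(xi), lam=theta, L=1.0))
            if prev is not None:
                assert np.all(out <= prev + 1e-15)
            prev = out

    @settings(derandomize=True, max_examples=200)
    @given(xi=st.floats(-10, 10), theta=st.floats(0, 5))
    def test_shrinkage_properties(self, xi, theta):
        """Soft threshold never grows magnitude, never flips sign, and is
        exactly zero inside the threshold band."""
        out = prox_step(np.array([xi]), np.array([1.0]), lam=theta, L=1.0)[0]
        assert abs(out) <= abs(xi)
        assert out * xi >= 0.0
        if abs(xi) <= theta:
            assert out == 0.0

    def test_per_position_weights(self):
        xi = np.array([1.0, 1.0])
        out = prox_step(xi, np.array([0.2, 0.8]), lam=1.0, L=1.0)
        assert np.allclose(out, [0.8, 0.2])


class TestIsta:
    def test_full_shrinkage_in_one_step(self, rng):
        X = rng.standard_normal((30, 10))
        y = rng.standard_normal(30)
        part = ViewPartition.from_widths([6, 4], primary_view=0)
        lam = float(np.max(np.abs(X.T @ y / 30))) / 0.4 + 1.0
        model = ista_solve(X, y, part, a1=0.4, lam=lam)
        assert np.all(model.omega == 0.0)
        assert model.iters_run == 1

    def test_lambda_zero_recovers_least_squares(self, rng):
        X = rng.standard_normal((60, 8))
        y = rng.standard_normal(60)
        part = ViewPartition.from_widths([5, 3], primary_view=0)
        model = ista_solve(X, y, part, a1=0.5, lam=0.0, max_iter=50000, tol=1e-12)
        w_star = np.linalg.solve(X.T @ X, X.T @ y)
        assert np.max(np.abs(model.omega - w_star)) < 1e-6

    def test_orthonormal_design_closed_form(self, rng):
        """With X^T X / N = I the lasso solution is the soft threshold of the
        least-squares solution."""
        N, D = 40, 8
        Q, _ = np.linalg.qr(rng.standard_normal((N, D)))
        X = Q * np.sqrt(N)
        y = rng.standard_normal(N)
        part = ViewPartition.from_widths([5, 3], primary_view=0)
        lam, a1 = 0.3, 0.4
        model = ista_solve(X, y, part, a1=a1, lam=lam, max_iter=20000, tol=1e-12)
        w_ls = X.T @ y / N
        want = prox_step(w_ls, part.weight_per_position(a1), lam, 1.0)
        assert np.max(np.abs(model.omega - want)) < 1e-8

    def test_objective_trace_nonincreasing(self, rng):
        X = rng.standard_normal((25, 40))
        y = rng.standard_normal(25)
        part = ViewPartition.from_widths([25, 15], primary_view=1)
        model = ista_solve(X, y, part, a1=0.2, lam=0.05)
        assert np.all(np.diff(model.objective_trace) <= 1e-10)

    def test_single_view_equals_plain_lasso(self, rng):
        """V=1 degenerates to an ordinary lasso with penalty lam * a1."""
        X = rng.standard_normal((30, 12))
        X, _, _ = standardize_columns(X)
        y = rng.standard_normal(30)
        y -= y.mean()
        part = ViewPartition.from_widths([12], primary_view=0)
        a1, lam = 0.6, 0.2
        model = ista_solve(X, y, part, a1=a1, lam=lam, max_iter=50000, tol=1e-12)
        part_all = ViewPartition.from_widths([6, 6], primary_view=0)
        ref = ista_solve(X, y, part_all, a1=0.5, lam=2 * a1 * lam,
                         max_iter=50000, tol=1e-12)
        assert np.max(np.abs(model.omega - ref.omega)) < 1e-8


class TestSupport:
    def _zero_model(self, widths):
        part = ViewPartition.from_widths(widths, primary_view=0)
        return SelectionModel(
            omega=np.zeros(sum(widths)), a1=0.2, lam=1.0, L=1.0, iters_run=1,
            objective_trace=np.zeros(2), converged=True, partition=part)

    def test_empty_support_falls_back_with_warning(self):
        model = self._zero_model([20, 15])
        with pytest.warns(UserWarning, match="falling back"):
            supports = select_support(model, [20, 15])
        assert len(supports[0]) == 10        # primary fallback top-10
        assert len(supports[1]) == 0         # auxiliary may stay empty

    def test_counts_entries_above_threshold(self):
        model = self._zero_model([5, 4])
        model.omega[[0, 2, 4]] = [0.5, -0.3, 1e-12]
        supports = select_support(model, [5, 4])
        assert supports[0].tolist() == [0, 2]


class TestRunPerViewSelection:
    def test_supports_are_view_subsets(self, tiny_synth):
        data, _ = tiny_synth
        reduced, result = run_per_view_selection(data, lam=0.5)
        assert len(result.support_per_view) == 3
        for sup, width in zip(result.support_per_view, data.view_widths):
            assert np.all((sup >= 0) & (sup < width))
        assert reduced.view_widths == [len(s) for s in result.support_per_view]

    def test_smaller_a1_keeps_more_primary_features(self):
        """Less punishment on the primary view (small a1) means a larger or
        equal primary support than heavy punishment (large a1)."""
        data, _ = generate_multiview(SynthConfig(seed=3))
        _, light = run_per_view_selection(data, a1=0.2, lam=0.3)
        _, heavy = run_per_view_selection(data, a1=0.8, lam=0.3)
        sizes_light = [len(s) for s in light.support_per_view]
        sizes_heavy = [len(s) for s in heavy.support_per_view]
        assert all(a >= b for a, b in zip(sizes_light, sizes_heavy))
        assert sum(sizes_light) > sum(sizes_heavy)

    def test_selection_ignores_non_training_rows(self, tiny_synth):
        data, _ = tiny_synth
        train_idx = np.arange(0, 40)
        _, a = run_per_view_selection(data, lam=0.5, train_idx=train_idx)
        corrupted = data.subset_subjects(np.arange(data.n_subjects))
        for view in corrupted.views:
            view.X[40:] += 100.0
        _, b = run_per_view_selection(corrupted, lam=0.5, train_idx=train_idx)
        for sa, sb in zip(a.support_per_view, b.support_per_view):
            assert np.array_equal(sa, sb)


def test_encode_labels_centred_pm_one():
    y, classes = encode_labels(np.array([0, 0, 1, 1, 1]))
    assert classes == (0, 1)
    raw = np.where(np.array([0, 0, 1, 1, 1]) == 1, 1.0, -1.0)
    assert np.allclose(y, raw - raw.mean())
    with pytest.raises(ValueError):
        encode_labels(np.array([0, 1, 2]))
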