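import numpy as np
import pytest
from sklearn.feature_selection import f_regression
from sklearn.linear_model import Ridge

from cvperm.estimator import (
    PipelineSpec,
    RidgeEstimator,
    UnivariateKBest,
    CollinearityFilter,
    compile_pipeline,
    filter_collinear,
    fit_pipeline,
    fit_ridge,
    grid_search,
    score_univariate,
    select_k_best,
)
from cvperm.exceptions import DegenerateDataError

from conftest import make_descriptor


def _spec(k=None, alpha=1e-4, grid=None, with_filter=False):
    steps = []
    if with_filter:
        steps.append(("filter", CollinearityFilter, {}))
    if k is not None:
        steps.append(("kbest", UnivariateKBest, {"k": k}))
    steps.append(("ridge", RidgeEstimator, {"alpha": alpha}))
    return PipelineSpec(steps=steps, grid_axes=grid)


class TestCollinearityFilter:
    def test_exact_duplicate_keeps_lowest_index(self):
        rng = np.random.default_rng(0)
        a, b = rng.standard_normal(20), rng.standard_normal(20)
        X = np.column_stack([a, a, b])
        np.testing.assert_array_equal(filter_collinear(X), [0, 2])

    def test_constant_column_dropped(self):
        rng = np.random.default_rng(1)
        X = np.column_stack([rng.standard_normal(20), np.full(20, 3.0)])
        np.testing.assert_array_equal(filter_collinear(X), [0])

    def test_scaled_copy_is_collinear(self):
        rng = np.random.default_rng(2)
        a = rng.standard_normal(30)
        X = np.column_stack([a, -2.5 * a + 1.0])
        np.testing.assert_array_equal(filter_collinear(X), [0])

    def test_independent_gaussians_all_kept(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((200, 50))
        # brute-force check of the premise: no pair near-collinear
        C = np.corrcoef(X, rowvar=False)
        np.fill_diagonal(C, 0.0)
        assert np.abs(C).max() < 1.0 - 1e-6
        np.testing.assert_array_equal(filter_collinear(X, 1e-6), np.arange(50))

    def test_all_constant_is_error(self):
        with pytest.raises(DegenerateDataError):
            filter_collinear(np.ones((10, 3)))


class TestUnivariateScores:
    def test_closed_form_matches_sklearn_f_regression(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((50, 8))
        y = X[:, 0] * 0.9 + rng.standard_normal(50)
        ours = score_univariate(X, y)
        theirs, _ = f_regression(X, y)
        np.testing.assert_allclose(ours, theirs, rtol=1e-9)

    def test_ranking_matches_correlation_strengths(self):
        """Columns engineered to correlate ~0.9/0.5/0.1 with y rank in that
        order under F = r^2 (n-2) / (1 - r^2)."""
        rng = np.random.default_rng(5)
        n = 50
        y = rng.standard_normal(n)
        yn = (y - y.mean()) / np.linalg.norm(y - y.mean())
        cols = []
        ones = np.ones(n) / np.sqrt(n)
        for rho in (0.9, 0.5, 0.1):
            e = rng.standard_normal(n)
            e -= yn * (yn @ e) + ones * (ones @ e)  # mean-zero, y-orthogonal
            e /= np.linalg.norm(e)
            cols.append(rho * yn + np.sqrt(1 - rho**2) * e)
        X = np.column_stack(cols)
        f = score_univariate(X, y)
        expected = np.array([r**2 * (n - 2) / (1 - r**2) for r in (0.9, 0.5, 0.1)])
        np.testing.assert_allclose(f, expected, rtol=1e-8)
        assert f[0] > f[1] > f[2]

    def test_perfect_correlation_ranks_first(self):
        rng = np.random.default_rng(6)
        X = rng.standard_normal((30, 3))
        y = X[:, 1].copy()
        f = score_univariate(X, y)
        assert np.isinf(f[1]) and np.argmax(f) == 1

    def test_orthogonal_column_scores_zero(self):
        y = np.array([1.0, -1.0, 1.0, -1.0])
        x = np.array([1.0, 1.0, -1.0, -1.0])
        assert score_univariate(x[:, None], y)[0] == pytest.approx(0.0, abs=1e-12)

    def test_zero_variance_target_is_error(self):
        with pytest.raises(DegenerateDataError):
            score_univariate(np.random.default_rng(0).standard_normal((10, 2)),
                             np.ones(10))


class TestSelectKBest:
    @pytest.mark.parametrize("scores,k,expected", [
        ([3.0, 1.0, 2.0], 2, [0, 2]),
        ([3.0, 1.0, 2.0], 3, [0, 1, 2]),
        ([1.0, 2.0, 2.0, 0.5], 2, [1, 2]),   # tie at the k-th place
        ([2.0, 2.0, 2.0], 2, [0, 1]),        # ties -> lowest indices
    ])
    def test_selection(self, scores, k, expected):
        np.testing.assert_array_equal(select_k_best(np.array(scores), k), expected)

    def test_k_too_large_is_error_not_truncation(self):
        with pytest.raises(ValueError, match="exceeds"):
            select_k_best(np.array([1.0, 2.0]), 3)


class TestRidge:
    def test_normal_equations_oracle(self):
        rng = np.random.default_rng(7)
        X = rng.standard_normal((20, 5))
        y = rng.standard_normal(20)
        w, c = fit_ridge(X, y, 0.1)
        Xc = X - X.mean(axis=0)
        yc = y - y.mean()
        w_direct = np.linalg.solve(Xc.T @ Xc + 0.1 * np.eye(5), Xc.T @ yc)
        np.testing.assert_allclose(w, w_direct, atol=1e-8)
        assert c == pytest.approx(y.mean() - X.mean(axis=0) @ w, abs=1e-10)

    def test_matches_sklearn_ridge(self):
        rng = np.random.default_rng(8)
        X = rng.standard_normal((30, 10))
        y = rng.standard_normal(30)
        w, c = fit_ridge(X, y, 2.5)
        sk = Ridge(alpha=2.5, solver="cholesky").fit(X, y)
        np.testing.assert_allclose(w, sk.coef_, atol=1e-8)
        assert c == pytest.approx(sk.intercept_, abs=1e-8)

    def test_dual_agrees_with_primal_when_k_exceeds_n(self):
        rng = np.random.default_rng(9)
        X = rng.standard_normal((15, 40))  # dual route
        y = rng.standard_normal(15)
        w, c = fit_ridge(X, y, 0.5)
        sk = Ridge(alpha=0.5).fit(X, y)
        np.testing.assert_allclose(w, sk.coef_, atol=1e-7)

    def test_infinite_shrinkage_predicts_mean(self):
        rng = np.random.default_rng(10)
        X = rng.standard_normal((25, 4))
        y = rng.standard_normal(25)
        w, c = fit_ridge(X, y, 1e12)
        np.testing.assert_allclose(w, 0.0, atol=1e-9)
        assert c == pytest.approx(y.mean(), abs=1e-6)

    def test_orthonormal_shrinkage_factor(self):
        """With orthonormal centered columns and y = X w*, ridge returns
        w* / (1 + alpha)."""
        rng = np.random.default_rng(11)
        A = rng.standard_normal((40, 5))
        A -= A.mean(axis=0)
        Q, _ = np.linalg.qr(A)
        w_star = np.array([1.0, -2.0, 0.5, 3.0, -1.0])
        y = Q @ w_star
        alpha = 0.7
        w, _ = fit_ridge(Q, y, alpha)
        np.testing.assert_allclose(w, w_star / (1 + alpha), atol=1e-8)

    def test_alpha_must_be_positive(self):
        with pytest.raises(ValueError):
            fit_ridge(np.ones((4, 1)), np.ones(4), 0.0)


class TestPipelineAndGrid:
    def test_deterministic_fit(self):
        rng = np.random.default_rng(12)
        X = rng.standard_normal((60, 30))
        y = rng.standard_normal(60)
        spec = _spec(k=10, with_filter=True)
        f1 = fit_pipeline(X, y, spec, seed_parts=(0, 0))
        f2 = fit_pipeline(X, y, spec, seed_parts=(0, 0))
        np.testing.assert_array_equal(f1.selected_columns, f2.selected_columns)
        np.testing.assert_array_equal(f1.ridge_coefficients, f2.ridge_coefficients)

    def test_selected_columns_subset_of_kept(self):
        rng = np.random.default_rng(13)
        X = rng.standard_normal((60, 30))
        X[:, 5] = X[:, 4]  # duplicate to engage the filter
        y = rng.standard_normal(60)
        fitted = fit_pipeline(X, y, _spec(k=10, with_filter=True))
        assert set(fitted.selected_columns) <= set(fitted.kept_columns)
        assert len(fitted.selected_columns) == 10

    def test_interpolation_when_k_ge_n_and_tiny_alpha(self):
        rng = np.random.default_rng(14)
        X = rng.standard_normal((20, 40))
        y = rng.standard_normal(20)
        fitted = fit_pipeline(X, y, _spec(k=40, alpha=1e-10))
        np.testing.assert_allclose(fitted.predict(X), y, atol=1e-4)

    def test_single_point_grid_is_that_point(self):
        rng = np.random.default_rng(15)
        X = rng.standard_normal((50, 10))
        y = rng.standard_normal(50)
        best, scores = grid_search(X, y, _spec(k=5, grid={"ridge__alpha": [0.3]}))
        assert best == {"ridge__alpha": 0.3}
        assert len(scores) == 1

    def test_grid_of_15_candidates_all_evaluated(self):
        """The 5 K-values x 3 alphas grid evaluates exactly 15 candidates."""
        rng = np.random.default_rng(16)
        X = rng.standard_normal((60, 40))
        y = rng.standard_normal(60)
        grid = {"kbest__k": [2, 5, 10, 20, 40], "ridge__alpha": [1e-4, 1e-2, 1.0]}
        _, scores = grid_search(X, y, _spec(k=5, grid=grid))
        assert len(scores) == 15

    def test_strong_signal_prefers_small_alpha(self):
        """With realizable signal and n >> K, the inner CV picks the small
        penalty; the two candidate scores are compared by the pipeline's own
        inner-CV evaluation."""
        rng = np.random.default_rng(17)
        X = rng.standard_normal((200, 5))
        y = X @ np.array([1.0, -2.0, 0.5, 1.5, -1.0])
        spec = _spec(k=5, grid={"ridge__alpha": [1e-4, 1e4]})
        best, scores = grid_search(X, y, spec)
        assert best == {"ridge__alpha": 1e-4}
        assert scores[(1e-4,)] > scores[(1e4,)]

    def test_planted_column_selected_consistently(self):
        """A single strongly predictive column among 50 is selected in
        essentially every replicate at n=200."""
        hits = 0
        n_rep = 100
        for rep in range(n_rep):
            rng = np.random.default_rng(1000 + rep)
            X = rng.standard_normal((200, 50))
            y = 1.5 * X[:, 7] + rng.standard_normal(200)
            fitted = fit_pipeline(X, y, _spec(k=5))
            hits += 7 in fitted.selected_columns
        assert hits / n_rep > 0.99

    def test_compile_resolves_descriptor_steps(self):
        d = make_descriptor(k=5, alpha=0.5)
        spec = compile_pipeline(d.pipeline, d.grid.axes if d.grid else None)
        names = [name for name, _, _ in spec.steps]
        assert names == ["kbest", "ridge"]
        assert spec.steps[1][2] == {"alpha": 0.5}
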