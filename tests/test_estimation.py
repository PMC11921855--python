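"""LASSO solver, cross-validated penalty selection, and CLPN assembly.

The solver is checked against two independent oracles: the closed-form
soft-threshold solution for a single predictor, and a proximal-gradient
(ISTA) minimizer of the same (1/2n)RSS + lambda*L1 objective run to tight
convergence.
"""

import warnings

import numpy as np
import pytest

from clpnet import SymptomPanel, fit_clpn, edge_summary, select_lambda_cv, solve_lasso, standardize_columns
from clpnet.estimation import lasso_objective, lambda_grid


def ista_lasso(X, y, lam, n_iter=200_000, tol=1e-12):
    """Independent proximal-gradient oracle for (1/2n)RSS + lam*L1."""
    n, k = X.shape
    step = 1.0 / (np.linalg.eigvalsh(X.T @ X / n).max())
    beta = np.zeros(k)
    for _ in range(n_iter):
        grad = X.T @ (X @ beta - y) / n
        new = beta - step * grad
        new = np.sign(new) * np.maximum(np.abs(new) - step * lam, 0.0)
        if np.max(np.abs(new - beta)) < tol:
            beta = new
            break
        beta = new
    return beta


class TestStandardize:
    def test_basic_column(self):
        z, means, scales, flags = standardize_columns(np.array([[1.0], [2.0], [3.0]]))
        np.testing.assert_allclose(z.ravel(), [-1, 0, 1])
        assert means[0] == 2 and scales[0] == 1

    def test_constant_column_flagged_and_zeroed(self):
        z, _, _, flags = standardize_columns(np.array([[5.0, 1.0], [5.0, 2.0], [5.0, 3.0]]))
        assert flags[0] and not flags[1]
        np.testing.assert_array_equal(z[:, 0], 0.0)

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((50, 3))
        z1, *_ = standardize_columns(x)
        z2, *_ = standardize_columns(z1)
        np.testing.assert_allclose(z1, z2, atol=1e-12)

    def test_needs_two_rows(self):
        with pytest.raises(ValueError):
            standardize_columns(np.array([[1.0, 2.0]]))


class TestSolveLasso:
    def test_above_lambda_max_all_zero(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((60, 5))
        y = rng.standard_normal(60)
        lam_max = np.max(np.abs(X.T @ y)) / 60
        beta = solve_lasso(X, y, lam_max * 1.0001)
        np.testing.assert_array_equal(beta, 0.0)

    @pytest.mark.parametrize("c", [0.6, -0.45, 0.05])
    def test_single_predictor_soft_threshold_closed_form(self, c):
        # x population-standardized so x'x = n and x'y/n = c exactly
        rng = np.random.default_rng(2)
        n = 200
        x = rng.standard_normal(n)
        x = (x - x.mean()) / x.std()
        e = rng.standard_normal(n)
        e -= e.mean()
        e -= x * (x @ e) / n  # orthogonal to x
        e /= np.sqrt((e @ e) / n)
        y = c * x + np.sqrt(max(1 - c * c, 0)) * e
        lam = 0.1
        expected = np.sign(c) * max(abs(c) - lam, 0.0)
        beta = solve_lasso(x[:, None], y, lam)
        assert beta[0] == pytest.approx(expected, abs=1e-6)

    def test_objective_matches_proximal_gradient_oracle(self):
        rng = np.random.default_rng(3)
        worst = 0.0
        for _ in range(20):
            X = rng.standard_normal((40, 3))
            beta_true = rng.normal(0, 1, 3) * rng.binomial(1, 0.7, 3)
            y = X @ beta_true + rng.normal(0, 0.5, 40)
            lam = float(rng.uniform(0.01, 0.3))
            ours = lasso_objective(X, y, solve_lasso(X, y, lam), lam)
            oracle = lasso_objective(X, y, ista_lasso(X, y, lam), lam)
            worst = max(worst, abs(ours - oracle))
        assert worst < 1e-6

    def test_zero_penalty_equals_ols(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((100, 4))
        y = X @ np.array([1.0, -0.5, 0.2, 0.0]) + rng.normal(0, 0.1, 100)
        ols = np.linalg.lstsq(X, y, rcond=None)[0]
        np.testing.assert_allclose(solve_lasso(X, y, 0.0), ols, atol=1e-6)

    def test_support_monotone_along_path(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((80, 6))
        y = X @ np.array([1.0, 0.8, 0.3, 0.0, 0.0, 0.0]) + rng.normal(0, 0.3, 80)
        sizes = [np.count_nonzero(solve_lasso(X, y, lam)) for lam in lambda_grid(X, y)]
        # grid is descending in lambda, so support size is non-decreasing
        assert all(a <= b for a, b in zip(sizes, sizes[1:]))

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            solve_lasso(np.array([[np.nan], [1.0]]), np.array([1.0, 2.0]), 0.1)


class TestSelectLambdaCV:
    def test_deterministic_under_fixed_seed(self):
        rng = np.random.default_rng(6)
        X, _, _, _ = standardize_columns(rng.standard_normal((120, 9)))
        y = rng.standard_normal(120)
        lam1, curve1 = select_lambda_cv(X, y, seed=99)
        lam2, curve2 = select_lambda_cv(X, y, seed=99)
        assert lam1 == lam2
        np.testing.assert_array_equal(curve1["cv_mse"], curve2["cv_mse"])

    def test_pure_noise_keeps_sparse_support(self):
        rng = np.random.default_rng(7)
        X, _, _, _ = standardize_columns(rng.standard_normal((500, 9)))
        y = rng.standard_normal(500)
        lam, _ = select_lambda_cv(X, y, seed=1)
        beta = solve_lasso(X, y, lam)
        assert np.count_nonzero(beta == 0) >= 7

    def test_recovers_single_strong_signal(self):
        rng = np.random.default_rng(8)
        X, _, _, _ = standardize_columns(rng.standard_normal((1000, 9)))
        y = 0.8 * X[:, 0] + rng.normal(0, 0.3, 1000)
        lam, _ = select_lambda_cv(X, y, seed=2)
        beta = solve_lasso(X, y, lam)
        assert beta[0] != 0
        assert beta[0] == pytest.approx(0.8, abs=0.1)

    def test_too_few_rows_for_folds(self):
        with pytest.raises(ValueError):
            select_lambda_cv(np.zeros((5, 2)), np.zeros(5), n_folds=10, seed=0)


class TestFitCLPN:
    def test_dominant_autoregression_when_t2_repeats_t1(self, identity_panel):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_clpn(identity_panel, covariates=False, seed=0)
        m = fit.edge_matrix
        for j in range(9):
            off = np.delete(m[:, j], j)
            assert m[j, j] > np.max(np.abs(off))

    def test_shape_and_covariate_segregation(self, chronic_panel):
        import pandas as pd

        panel, _ = chronic_panel
        sub = panel.subset(np.arange(300))
        sub.covariates = pd.DataFrame({"sex": np.tile([0, 1], 150), "age": np.linspace(18, 24, 300)})
        fit = fit_clpn(sub, covariates=True, seed=1)
        assert fit.edge_matrix.shape == (9, 9)
        assert list(fit.covariate_effects.index) == ["sex", "age"]
        assert fit.covariate_effects.shape == (2, 9)
        assert (fit.lambdas >= 0).all()

    def test_permutation_equivariance(self, chronic_panel):
        panel, _ = chronic_panel
        sub = panel.subset(np.arange(400))
        perm = np.array([3, 1, 4, 0, 8, 6, 2, 7, 5])
        permuted = SymptomPanel(
            subject_id=sub.subject_id,
            scores_t1=sub.scores_t1[:, perm],
            scores_t2=sub.scores_t2[:, perm],
            item_labels=tuple(np.array(sub.item_labels)[perm]),
        )
        # frozen penalties isolate the equivariance of the solve itself from
        # fold-assignment randomness tied to target position
        base = fit_clpn(sub, covariates=False, seed=0)
        lam_perm = base.lambdas[perm]
        fit_p = fit_clpn(permuted, covariates=False, seed=0, lambdas=lam_perm)
        fit_b = fit_clpn(sub, covariates=False, seed=0, lambdas=base.lambdas)
        np.testing.assert_allclose(
            fit_p.edge_matrix, fit_b.edge_matrix[np.ix_(perm, perm)], atol=1e-8
        )

    def test_zero_variance_target_zeroed_with_warning(self):
        rng = np.random.default_rng(9)
        t1 = rng.integers(0, 4, size=(100, 9))
        t2 = rng.integers(0, 4, size=(100, 9))
        t2[:, 4] = 2  # constant outcome column
        panel = SymptomPanel(np.arange(100), t1, t2)
        with pytest.warns(UserWarning, match="degenerate"):
            fit = fit_clpn(panel, covariates=False, seed=0)
        np.testing.assert_array_equal(fit.edge_matrix[:, 4], 0.0)
        assert 4 in fit.degenerate_targets

    def test_serialization_round_trip(self, chronic_panel):
        from clpnet.estimation import CLPNFit

        panel, _ = chronic_panel
        fit = fit_clpn(panel.subset(np.arange(200)), covariates=False, seed=0)
        back = CLPNFit.from_dict(fit.to_dict())
        np.testing.assert_array_equal(back.edge_matrix, fit.edge_matrix)
        assert back.item_labels == fit.item_labels


class TestEdgeSummary:
    def test_all_zero_matrix(self):
        import pandas as pd
        from clpnet.estimation import CLPNFit
        from clpnet.panel import ITEM_LABELS

        fit = CLPNFit(np.zeros((9, 9)), pd.DataFrame(), np.zeros(9), np.zeros(9),
                      10, 0, ITEM_LABELS)
        s = edge_summary(fit)
        assert s["n_nonzero_cross_lagged"] == 0
        assert s["n_possible_cross_lagged"] == 72

    def test_strongest_edges_located(self):
        import pandas as pd
        from clpnet.estimation import CLPNFit
        from clpnet.panel import ITEM_LABELS

        m = np.zeros((9, 9))
        m[8, 8] = 0.345  # autoregressive maximum at suicidal ideation
        m[3, 0] = 0.105  # lack of energy -> anhedonia
        fit = CLPNFit(m, pd.DataFrame(), np.zeros(9), np.zeros(9), 10, 0, ITEM_LABELS)
        s = edge_summary(fit)
        assert s["max_autoregressive"] == {"node": "suicidal_ideation", "weight": 0.345}
        assert s["max_cross_lagged"]["source"] == "lack_of_energy"
        assert s["max_cross_lagged"]["target"] == "anhedonia"
        assert s["max_cross_lagged"]["weight"] == 0.105
        assert s["n_nonzero_cross_lagged"] == 1
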