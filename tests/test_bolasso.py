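"""Penalized conditional logistic path, CV one-SE rule, BoLasso selection."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar

from conftest import simulate_pair_differences
from metabomatch import cv_lambda_1se, fit_conditional_logistic
from metabomatch.bolasso import PenalizedPairedLogit, bolasso, clogit_lasso_path


@pytest.fixture(scope="module")
def D_small():
    rng = np.random.default_rng(0)
    return simulate_pair_differences(rng, 120, [0.8, -0.5, 0.0, 0.0, 0.0, 0.0])


class TestPath:
    def test_lambda_max_formula_and_null_solution(self, D_small):
        m = PenalizedPairedLogit(D_small)
        n = D_small.shape[0]
        assert m.lambda_max == pytest.approx(np.max(np.abs(D_small.sum(axis=0))) / (2 * n))
        path = m.fit_path(np.array([m.lambda_max * 1.5, m.lambda_max]))
        assert (path.coefs.to_numpy() == 0.0).all()

    def test_lambda_zero_matches_unpenalized_mle(self, D_small):
        path = clogit_lasso_path(D_small, np.array([0.0]))
        mle = fit_conditional_logistic(D_small)
        np.testing.assert_allclose(path.coefs.iloc[0].values, mle.params.values, atol=1e-4)

    def test_single_feature_matches_golden_section_oracle(self):
        rng = np.random.default_rng(4)
        d = simulate_pair_differences(rng, 80, [0.6])
        lam = 0.05
        n = d.shape[0]

        def objective(b):
            return np.logaddexp(0.0, -(d[:, 0] * b)).mean() + lam * abs(b)

        oracle = minimize_scalar(objective, bracket=(-2, 0, 2), method="golden",
                                 options={"xtol": 1e-10}).x
        path = clogit_lasso_path(d, np.array([lam]))
        assert path.coefs.iloc[0, 0] == pytest.approx(oracle, abs=1e-6)
        assert n == 80

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_kkt_conditions_along_path(self, seed):
        rng = np.random.default_rng(seed)
        D = simulate_pair_differences(rng, 100, [0.7, 0.0, -0.4, 0.0, 0.0])
        m = PenalizedPairedLogit(D)
        path = m.fit_path(n_lambdas=25)
        for lam, (_, beta) in zip(path.lambdas, path.coefs.iterrows()):
            b = beta.to_numpy()
            g = m._gradient(b)
            nz = b != 0
            assert (np.abs(g[~nz]) <= lam + 1e-6).all()
            if nz.any():
                assert np.abs(g[nz] + lam * np.sign(b[nz])).max() <= 1e-6

    def test_support_weakly_grows_down_the_path(self, D_small):
        path = clogit_lasso_path(D_small, n_lambdas=30)
        nnz = (path.coefs.to_numpy() != 0).sum(axis=1)
        # minor local violations are tolerated but the trend must hold
        assert nnz[0] == 0 and nnz[-1] >= nnz[5]

    def test_path_continuity_with_warm_starts(self, D_small):
        path = clogit_lasso_path(D_small, n_lambdas=50)
        jumps = np.abs(np.diff(path.coefs.to_numpy(), axis=0)).max(axis=1)
        assert jumps.max() < 0.25

    def test_agrees_with_sklearn_on_augmented_design(self, D_small):
        from sklearn.linear_model import LogisticRegression

        lam = 0.02
        n = D_small.shape[0]
        path = clogit_lasso_path(D_small, np.array([lam]))
        Xaug = np.vstack([D_small, -D_small])
        yaug = np.r_[np.ones(n), np.zeros(n)]
        ref = LogisticRegression(penalty="l1", C=1.0 / (2 * n * lam), solver="liblinear",
                                 fit_intercept=False, tol=1e-10, max_iter=5000)
        ref.fit(Xaug, yaug)
        np.testing.assert_allclose(path.coefs.iloc[0].values, ref.coef_[0], atol=2e-4)


class TestCV:
    def test_lambda_1se_at_least_lambda_min(self, D_small):
        cv = cv_lambda_1se(D_small, folds=5, seed=3)
        assert cv.lambda_1se >= cv.lambda_min
        assert cv.lambda_1se in cv.lambdas and cv.lambda_min in cv.lambdas

    def test_pure_noise_selects_near_empty_models(self):
        near_empty = 0
        for s in range(5):
            rng = np.random.default_rng(200 + s)
            D = rng.standard_normal((100, 10)) * np.sqrt(2)
            cv = cv_lambda_1se(D, folds=5, seed=s)
            path = clogit_lasso_path(D, cv.lambdas)
            near_empty += int(path.support_at(cv.lambda_1se).sum() <= 2)
        assert near_empty >= 4

    def test_duplicating_pairs_leaves_lambda_max_unchanged(self, D_small):
        m1 = PenalizedPairedLogit(D_small)
        m2 = PenalizedPairedLogit(np.vstack([D_small, D_small]))
        assert m1.lambda_max == pytest.approx(m2.lambda_max)

    def test_too_few_pairs_for_folds_raises(self):
        with pytest.raises(ValueError, match="fold"):
            cv_lambda_1se(np.random.default_rng(0).standard_normal((3, 2)), folds=5)


class TestBolasso:
    def test_single_bootstrap_gives_indicator_frequencies(self, D_small):
        rep = bolasso(D_small, B=1, seed=5)
        assert set(np.unique(rep.frequencies.values)).issubset({0.0, 1.0})

    def test_strong_predictor_reaches_threshold_small_scale(self):
        rng = np.random.default_rng(7)
        D = pd.DataFrame(simulate_pair_differences(rng, 300, [1.0] + [0.0] * 7),
                         columns=[f"v{j}" for j in range(8)])
        rep = bolasso(D, B=20, seed=8)
        assert rep.frequencies["v0"] >= 0.9
        assert rep.selected == ["v0"] or "v0" in rep.selected
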