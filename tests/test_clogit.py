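"""Conditional logistic estimator against closed-form and numeric oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from conftest import simulate_pair_differences
from metabomatch import (
    PairedConditionalLogit,
    fit_conditional_logistic,
    fit_unconditional_adjusted,
    impute_covariates,
    lrt_heterogeneity,
    or_per_sd,
    restrict_pairs,
    standardize_cpeptide,
)
from metabomatch.clogit import SeparationError, subgroup_per_pair
from metabomatch.data import MatchedCohort


def grid_mle(D: np.ndarray, span: float = 4.0) -> np.ndarray:
    """Brute-force conditional-likelihood maximizer by nested grid refinement."""

    def ll(beta):
        return -np.logaddexp(0.0, -(D @ beta)).sum()

    k = D.shape[1]
    center, width = np.zeros(k), span
    for _ in range(7):  # final grid spacing ~3e-5: resolves the MLE to <1e-4
        axes = [np.linspace(c - width, c + width, 21) for c in center]
        grids = np.meshgrid(*axes, indexing="ij")
        B = np.stack([g.ravel() for g in grids], axis=1)
        vals = -np.logaddexp(0.0, -(D @ B.T)).sum(axis=0)
        center = B[np.argmax(vals)]
        width *= 0.2
    return center


class TestMLE:
    def test_mcnemar_closed_form(self):
        """Single binary exposure: MLE = ratio of discordant pair counts."""
        # 10 discordant pairs with the case exposed, 5 the reverse, 7 concordant
        D = np.array([[1.0]] * 10 + [[-1.0]] * 5 + [[0.0]] * 7)
        fit = fit_conditional_logistic(D)
        assert np.exp(fit.params.iloc[0]) == pytest.approx(10.0 / 5.0, abs=1e-9)

    @pytest.mark.parametrize("seed,n,k", [(0, 6, 2), (1, 8, 2), (2, 8, 1)])
    def test_matches_grid_search_oracle(self, seed, n, k):
        rng = np.random.default_rng(seed)
        D = rng.standard_normal((n, k))
        fit = fit_conditional_logistic(D)
        np.testing.assert_allclose(fit.params.values, grid_mle(D), atol=1e-4)

    def test_role_swap_negates_coefficients(self):
        rng = np.random.default_rng(4)
        D = rng.standard_normal((30, 3))
        f1, f2 = fit_conditional_logistic(D), fit_conditional_logistic(-D)
        np.testing.assert_allclose(f1.params.values, -f2.params.values, atol=1e-8)
        np.testing.assert_allclose(f1.bse.values, f2.bse.values, atol=1e-8)

    def test_location_shift_absorbed_by_differences(self, small_dataset):
        panel, cohort, _ = small_dataset
        from metabomatch import transform_standardize

        X = transform_standardize(panel).X
        f1 = PairedConditionalLogit.from_cohort(cohort, X).fit()
        f2 = PairedConditionalLogit.from_cohort(cohort, X + 3.7).fit()
        np.testing.assert_allclose(f1.params.values, f2.params.values, atol=1e-10)

    def test_separation_raises(self):
        D = np.ones((12, 1))  # every case has the larger value
        with pytest.raises(SeparationError):
            fit_conditional_logistic(D)

    def test_all_zero_column_raises(self):
        D = np.column_stack([np.random.default_rng(0).standard_normal(10), np.zeros(10)])
        with pytest.raises(ValueError, match="all-zero"):
            fit_conditional_logistic(D)

    def test_agrees_with_statsmodels(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(9)
        D = simulate_pair_differences(rng, 120, [0.4, -0.2, 0.0])
        fit = fit_conditional_logistic(D)
        base = rng.standard_normal((120, 3))
        y = np.r_[np.ones(120), np.zeros(120)]
        X = np.vstack([base + D, base])
        groups = np.r_[np.arange(120), np.arange(120)]
        ref = sm.ConditionalLogit(y, X, groups=groups).fit(disp=0)
        np.testing.assert_allclose(fit.params.values, ref.params, atol=1e-4)
        np.testing.assert_allclose(fit.bse.values, ref.bse, atol=1e-4)


class TestORTable:
    def test_wald_interval_at_null(self):
        model = PairedConditionalLogit(np.array([[1.0], [-1.0]]))
        from metabomatch.clogit import PairedConditionalLogitResults

        res = PairedConditionalLogitResults(
            model=model,
            params=pd.Series([0.0], index=["x0"]),
            cov_params_frame=pd.DataFrame([[0.01]], index=["x0"], columns=["x0"]),
            llf=0.0,
            converged=True,
            n_iter=1,
        )
        orr, lo, hi, p = or_per_sd(res, "x0")
        assert orr == pytest.approx(1.0)
        assert lo == pytest.approx(np.exp(-stats.norm.ppf(0.975) * 0.1), rel=1e-6)
        assert hi == pytest.approx(np.exp(stats.norm.ppf(0.975) * 0.1), rel=1e-6)
        assert p == pytest.approx(1.0)

    def test_pvalue_matches_normal_cdf(self):
        rng = np.random.default_rng(2)
        fit = fit_conditional_logistic(simulate_pair_differences(rng, 200, [0.3]))
        z = fit.params.iloc[0] / fit.bse.iloc[0]
        assert fit.pvalues.iloc[0] == pytest.approx(2 * stats.norm.sf(abs(z)))

    def test_ci_brackets_or(self):
        rng = np.random.default_rng(3)
        fit = fit_conditional_logistic(simulate_pair_differences(rng, 100, [0.5, -0.5]))
        tab = fit.or_table()
        assert ((tab["ci_low"] <= tab["OR"]) & (tab["OR"] <= tab["ci_high"])).all()


class TestHeterogeneity:
    def test_single_level_is_null_test(self):
        rng = np.random.default_rng(0)
        D = pd.DataFrame({"x": simulate_pair_differences(rng, 40, [0.3])[:, 0]})
        res = lrt_heterogeneity(D, "x", pd.Series(["all"] * 40, index=D.index))
        assert res.lrt_stat == 0.0 and res.pvalue == 1.0

    def test_df_is_levels_minus_one(self):
        rng = np.random.default_rng(1)
        D = pd.DataFrame({"x": simulate_pair_differences(rng, 90, [0.3])[:, 0]})
        labels = pd.Series(np.repeat(["a", "b", "c"], 30), index=D.index)
        assert lrt_heterogeneity(D, "x", labels).df == 2

    def test_power_against_planted_heterogeneity(self):
        """ORs 1.0 vs 2.0 with 400 pairs each: LRT rejects far more than 80%."""
        hits = 0
        for s in range(30):
            rng = np.random.default_rng(100 + s)
            d0 = simulate_pair_differences(rng, 400, [0.0])
            d1 = simulate_pair_differences(rng, 400, [np.log(2.0)])
            D = pd.DataFrame({"x": np.r_[d0[:, 0], d1[:, 0]]})
            labels = pd.Series(np.repeat(["g0", "g1"], 400), index=D.index)
            hits += int(lrt_heterogeneity(D, "x", labels).pvalue <= 0.05)
        assert hits >= 24  # >= 80% empirical power

    def test_within_pair_variation_directed_to_unconditional(self, small_dataset):
        _, cohort, _ = small_dataset
        with pytest.raises(ValueError, match="unconditional"):
            subgroup_per_pair(cohort, "bmi")


class TestUnconditional:
    @staticmethod
    def _null_cohort(seed, n_pairs=300):
        from metabomatch import SimulationConfig, generate_cohort, transform_standardize

        cfg = SimulationConfig(n_pairs=n_pairs, n_metabolites=2, block_sizes=[1, 1],
                               within_block_corr=0.0, bmi_log_or=0.0, seed=seed)
        panel, cohort, _ = generate_cohort(cfg)
        return cohort, transform_standardize(panel).X

    def test_null_strata_or_near_one(self):
        logors = []
        for s in range(12):
            cohort, X = self._null_cohort(1000 + s)
            strat = pd.Series(np.where(cohort.table["bmi"] > 26, "high", "low"),
                              index=cohort.table.index, name="bmi_class")
            res = fit_unconditional_adjusted(cohort, X["M000"], strat)
            logors += list(np.log(res.per_stratum["OR"]))
        mean, se = np.mean(logors), np.std(logors, ddof=1) / np.sqrt(len(logors))
        assert abs(mean) <= 2 * se + 0.02

    def test_agrees_with_conditional_when_strata_fully_captured(self):
        cohort, X = self._null_cohort(77, n_pairs=2000)
        strat = pd.Series("all", index=cohort.table.index, name="overall")
        res = fit_unconditional_adjusted(cohort, X["M000"], strat)
        cond = PairedConditionalLogit.from_cohort(cohort, X[["M000"]]).fit()
        assert abs(np.log(res.per_stratum["OR"].iloc[0]) - cond.params.iloc[0]) < 0.05

    def test_single_class_stratum_raises(self, small_dataset):
        _, cohort, _ = small_dataset
        x = pd.Series(0.0, index=cohort.table.index) + np.arange(len(cohort.table))
        strat = pd.Series(np.where(cohort.table["role"] == "case", "a", "b"),
                          index=cohort.table.index)
        with pytest.raises(SeparationError):
            fit_unconditional_adjusted(cohort, x, strat)


class TestRestrictions:
    def test_lag_restriction_tests_case_only(self, small_dataset):
        _, cohort, _ = small_dataset
        out = restrict_pairs(cohort, lambda r: r["lag_years"] > 2.0, apply_to="case")
        lag = out.cases()["lag_years"]
        assert (lag > 2.0).all()
        assert out.n_pairs == (cohort.cases()["lag_years"] > 2.0).sum()

    def test_true_predicate_is_identity(self, small_dataset):
        _, cohort, _ = small_dataset
        out = restrict_pairs(cohort, lambda r: True)
        pd.testing.assert_frame_equal(out.table, cohort.table)

    def test_false_predicate_raises(self, small_dataset):
        _, cohort, _ = small_dataset
        with pytest.raises(ValueError, match="every pair"):
            restrict_pairs(cohort, lambda r: False)

    def test_pair_dropped_if_either_member_fails(self, small_dataset):
        _, cohort, _ = small_dataset
        out = restrict_pairs(cohort, lambda r: not r["diabetes"], apply_to="both")
        bad_pairs = set(cohort.table.loc[cohort.table["diabetes"].astype(bool), "pair_id"])
        assert set(out.table["pair_id"]).isdisjoint(bad_pairs)


class TestCovariatePrep:
    def test_cpeptide_phasewise_zscore(self):
        vals = pd.Series([1.0, 2.0, 3.0, 10.0, 20.0, 30.0])
        phases = pd.Series(["a"] * 3 + ["b"] * 3)
        z = standardize_cpeptide(vals, phases)
        np.testing.assert_allclose(z[:3], z[3:], atol=1e-12)  # equal ranks, equal scores
        for ph in ("a", "b"):
            grp = z[phases == ph]
            assert grp.mean() == pytest.approx(0.0, abs=1e-12)
            assert grp.std(ddof=1) == pytest.approx(1.0)

    def test_constant_phase_raises(self):
        with pytest.raises(ValueError, match="zero variance"):
            standardize_cpeptide(pd.Series([1.0, 1.0]), pd.Series(["a", "a"]))

    def test_imputation_rules(self, small_dataset):
        _, cohort, _ = small_dataset
        tab = cohort.table.copy()
        n = len(tab)
        tab.iloc[: int(0.03 * n), tab.columns.get_loc("bmi")] = np.nan  # 3% continuous
        tab.iloc[: int(0.10 * n), tab.columns.get_loc("smoking")] = np.nan  # 10% categorical
        cohort2 = MatchedCohort(tab, cohort.matching_factors)
        out, report = impute_covariates(cohort2, continuous=["bmi"], categorical=["smoking"])
        acts = dict(zip(report["covariate"], report["action"]))
        assert acts["bmi"] == "median" and acts["smoking"] == "missing_category"
        assert not out.table["bmi"].isna().any()
        assert (out.table["smoking"] == "missing").sum() == int(0.10 * n)

    def test_no_missing_is_identity(self, small_dataset):
        _, cohort, _ = small_dataset
        out, report = impute_covariates(cohort, continuous=["bmi"], categorical=["smoking"])
        pd.testing.assert_frame_equal(out.table, cohort.table)

    def test_heavily_missing_continuous_raises(self, small_dataset):
        _, cohort, _ = small_dataset
        tab = cohort.table.copy()
        tab.loc[tab.index[: len(tab) // 2], "wc"] = np.nan
        with pytest.raises(ValueError, match="bin"):
            impute_covariates(MatchedCohort(tab, cohort.matching_factors),
                              continuous=["wc"], categorical=[])
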