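"""Conditional logistic regression for 1:1 matched case-control pairs.

For 1:1 matched sets the conditional likelihood reduces to an
intercept-free logistic likelihood on within-pair case-minus-control
differences ``d_i``::

    L(beta) = prod_i sigma(beta' d_i),    sigma(t) = 1 / (1 + exp(-t))

Matching-stratum effects cancel in the differences, so only the exposure
and adjustment covariates enter.  With features standardized to unit SD
upstream, ``exp(beta_j)`` is the odds ratio per one SD increase in log
concentration.

The module also provides the surrounding epidemiological machinery:
likelihood-ratio heterogeneity tests across subgroups, an unconditional
logistic fallback for strata defined by matching-incompatible variables
(BMI/WC classes), pair-preserving sensitivity restrictions, phase-wise
C-peptide standardization and the median/mode covariate imputation rules.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from .data import CASE, MatchedCohort, PairDifferences

__all__ = [
    "PairedConditionalLogit",
    "PairedConditionalLogitResults",
    "ConvergenceError",
    "SeparationError",
    "fit_conditional_logistic",
    "or_per_sd",
    "lrt_heterogeneity",
    "HeterogeneityResult",
    "fit_unconditional_adjusted",
    "restrict_pairs",
    "standardize_cpeptide",
    "impute_covariates",
]

_Z975 = stats.norm.ppf(0.975)


class ConvergenceError(RuntimeError):
    pass


class SeparationError(RuntimeError):
    """Likelihood unbounded: estimates diverge (complete separation)."""


def _as_matrix(D) -> tuple[np.ndarray, list[str]]:
    if isinstance(D, PairDifferences):
        return D.values, D.feature_names
    if isinstance(D, pd.DataFrame):
        return D.to_numpy(dtype=float), list(D.columns)
    D = np.atleast_2d(np.asarray(D, dtype=float))
    return D, [f"x{j}" for j in range(D.shape[1])]


class PairedConditionalLogit:
    """Model object for the 1:1 pair-difference conditional likelihood.

    Parameters
    ----------
    D : PairDifferences, DataFrame or (n_pairs, k) array
        Case-minus-control differences of the model features.
    """

    def __init__(self, D, feature_names: list[str] | None = None):
        self.D, names = _as_matrix(D)
        self.feature_names = list(feature_names) if feature_names is not None else names
        if self.D.ndim != 2 or self.D.shape[0] < 1:
            raise ValueError("need at least one pair")
        if not np.isfinite(self.D).all():
            raise ValueError("non-finite pair differences")
        zero = ~np.any(self.D != 0, axis=0)
        if zero.any():
            raise ValueError(
                f"all-zero difference column(s): {[self.feature_names[j] for j in np.flatnonzero(zero)]}"
            )

    @classmethod
    def from_cohort(cls, cohort: MatchedCohort, X: pd.DataFrame) -> "PairedConditionalLogit":
        return cls(PairDifferences.from_cohort(cohort, X))

    # -- likelihood --------------------------------------------------------
    def loglike(self, beta: np.ndarray) -> float:
        eta = self.D @ beta
        # sum of log sigma(eta), computed stably
        return float(-np.logaddexp(0.0, -eta).sum())

    def score(self, beta: np.ndarray) -> np.ndarray:
        eta = self.D @ beta
        return self.D.T @ (1.0 - expit(eta))

    def hessian(self, beta: np.ndarray) -> np.ndarray:
        mu = expit(self.D @ beta)
        w = mu * (1.0 - mu)
        return -(self.D * w[:, None]).T @ self.D

    def fit(
        self,
        start: np.ndarray | None = None,
        maxiter: int = 50,
        gtol: float = 1e-8,
        xtol: float = 1e-10,
        separation_bound: float = 15.0,
    ) -> "PairedConditionalLogitResults":
        """Newton-Raphson with step halving on the conditional likelihood.

        Converges when the largest score component falls below ``gtol`` or
        the step below ``xtol``; flags complete separation when a
        standardized coefficient exceeds ``separation_bound`` while the
        score has not vanished.
        """
        k = self.D.shape[1]
        beta = np.zeros(k) if start is None else np.asarray(start, dtype=float).copy()
        ll = self.loglike(beta)
        converged = False
        it = 0
        for it in range(1, maxiter + 1):
            g = self.score(beta)
            score_small = np.max(np.abs(g)) < gtol
            H = self.hessian(beta)
            try:
                step = np.linalg.solve(H, -g)
            except np.linalg.LinAlgError:
                step = np.linalg.lstsq(H, -g, rcond=None)[0]
            # step halving on non-increase of the likelihood
            t = 1.0
            for _ in range(30):
                cand = beta + t * step
                ll_new = self.loglike(cand)
                if ll_new >= ll - 1e-12:
                    break
                t /= 2.0
            beta, ll = beta + t * step, ll_new
            if score_small:
                # quadratic polish applied; score is now at machine precision
                converged = True
                break
            if np.max(np.abs(beta)) > separation_bound and np.max(np.abs(self.score(beta))) > gtol:
                raise SeparationError(
                    f"estimates diverging (|beta| > {separation_bound}); the conditional "
                    "likelihood appears unbounded (complete separation). "
                    f"beta = {dict(zip(self.feature_names, np.round(beta, 2)))}"
                )
            if np.max(np.abs(t * step)) < xtol:
                converged = np.max(np.abs(self.score(beta))) < 1e-4
                break
        if not converged and np.max(np.abs(self.score(beta))) < gtol:
            converged = True
        info = -self.hessian(beta)
        try:
            cov = np.linalg.inv(info)
        except np.linalg.LinAlgError:
            cov = np.linalg.pinv(info)
        return PairedConditionalLogitResults(
            model=self,
            params=pd.Series(beta, index=self.feature_names),
            cov_params_frame=pd.DataFrame(cov, index=self.feature_names, columns=self.feature_names),
            llf=self.loglike(beta),
            converged=bool(converged),
            n_iter=it,
        )


@dataclass
class PairedConditionalLogitResults:
    """Fitted conditional logistic model: estimates, uncertainty, OR table."""

    model: PairedConditionalLogit
    params: pd.Series
    cov_params_frame: pd.DataFrame
    llf: float
    converged: bool
    n_iter: int

    @property
    def bse(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov_params_frame.values)), index=self.params.index)

    def cov_params(self) -> pd.DataFrame:
        return self.cov_params_frame

    @property
    def n_pairs(self) -> int:
        return self.model.D.shape[0]

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        z = stats.norm.ppf(1 - alpha / 2)
        return pd.DataFrame(
            {"lower": self.params - z * self.bse, "upper": self.params + z * self.bse}
        )

    @property
    def pvalues(self) -> pd.Series:
        z = self.params / self.bse
        return pd.Series(2 * stats.norm.sf(np.abs(z)), index=self.params.index)

    def or_table(self, alpha: float = 0.05) -> pd.DataFrame:
        """Per-feature odds ratio (per SD for standardized features), Wald CI and p."""
        ci = self.conf_int(alpha)
        return pd.DataFrame(
            {
                "OR": np.exp(self.params),
                "ci_low": np.exp(ci["lower"]),
                "ci_high": np.exp(ci["upper"]),
                "p": self.pvalues,
                "n_pairs": self.n_pairs,
            }
        )

    def summary(self) -> str:
        head = (
            "Conditional logistic regression (1:1 matched pairs)\n"
            f"  pairs: {self.n_pairs}   features: {len(self.params)}\n"
            f"  log-likelihood: {self.llf:.4f}   converged: {self.converged} "
            f"({self.n_iter} iterations)\n"
        )
        tab = self.or_table().copy()
        tab.insert(0, "beta", self.params)
        tab.insert(1, "se", self.bse)
        return head + tab.to_string(float_format=lambda v: f"{v:.4f}")


def fit_conditional_logistic(D, **kwargs) -> PairedConditionalLogitResults:
    """Fit the pair-difference conditional logistic model (convenience)."""
    return PairedConditionalLogit(D).fit(**kwargs)


def or_per_sd(fit: PairedConditionalLogitResults, feature: str) -> tuple[float, float, float, float]:
    """(OR, CI_low, CI_high, p) for one standardized feature."""
    if not fit.converged:
        raise ConvergenceError("fit did not converge; per-SD OR not reliable")
    row = fit.or_table().loc[feature]
    return float(row["OR"]), float(row["ci_low"]), float(row["ci_high"]), float(row["p"])


# ---------------------------------------------------------------------------
# heterogeneity across subgroups
# ---------------------------------------------------------------------------


@dataclass
class HeterogeneityResult:
    subgroup: str
    per_level: pd.DataFrame  # level -> OR, ci_low, ci_high, n_pairs
    lrt_stat: float
    df: int
    pvalue: float


def subgroup_per_pair(cohort: MatchedCohort, column: str, member: str = "both") -> pd.Series:
    """Per-pair subgroup labels from a cohort column.

    ``member="both"`` requires the label constant within each pair (a
    matching-compatible variable) and raises otherwise; ``member="case"``
    takes the case's value (e.g. age at diagnosis, lag time, histology).
    """
    cases, controls = cohort.paired_frames()
    if member == "case":
        return pd.Series(cases[column].values, index=cases["pair_id"].values)
    vc, vk = cases[column].values, controls[column].values
    differ = ~(pd.isna(vc) & pd.isna(vk)) & (vc != vk)
    if differ.any():
        raise ValueError(
            f"subgroup {column!r} varies within {differ.sum()} pair(s); use the "
            "unconditional path (fit_unconditional_adjusted) for such variables"
        )
    return pd.Series(vc, index=cases["pair_id"].values)


def lrt_heterogeneity(D, exposure: str, subgroup: pd.Series) -> HeterogeneityResult:
    """Likelihood-ratio test of effect heterogeneity across subgroups.

    Compares the model with exposure x subgroup interactions (one slope per
    level) against the common-slope model; the statistic is ``2 * delta
    log-likelihood`` on ``levels - 1`` degrees of freedom.  ``subgroup``
    must be indexed by pair id (see :func:`subgroup_per_pair`).
    """
    if isinstance(D, PairDifferences):
        d = D.frame[exposure]
    else:
        d = D[exposure]
    labels = subgroup.reindex(d.index)
    if labels.isna().any():
        keep = labels.notna()
        d, labels = d[keep], labels[keep]
    levels = sorted(pd.unique(labels))
    reduced = PairedConditionalLogit(d.to_frame()).fit()
    if len(levels) == 1:
        per = reduced.or_table()
        per.index = [levels[0]]
        return HeterogeneityResult(subgroup.name or "subgroup", per, 0.0, 1, 1.0)
    full_cols = {
        f"{exposure}[{lev}]": d.values * (labels.values == lev) for lev in levels
    }
    full = PairedConditionalLogit(pd.DataFrame(full_cols, index=d.index)).fit()
    lrt = max(0.0, 2.0 * (full.llf - reduced.llf))
    df = len(levels) - 1
    rows = []
    for lev in levels:
        sub_fit = PairedConditionalLogit(d[labels == lev].to_frame()).fit()
        rows.append(sub_fit.or_table().iloc[0])
    per = pd.DataFrame(rows, index=levels)
    return HeterogeneityResult(
        subgroup.name or "subgroup", per, lrt, df, float(stats.chi2.sf(lrt, df))
    )


# ---------------------------------------------------------------------------
# unconditional fallback for matching-incompatible strata (BMI/WC classes)
# ---------------------------------------------------------------------------


@dataclass
class UnconditionalResult:
    stratum_variable: str
    per_stratum: pd.DataFrame  # stratum -> OR, ci_low, ci_high, p, n
    interaction_p: float


def fit_unconditional_adjusted(
    cohort: MatchedCohort, x: pd.Series, stratum: pd.Series, matching_factors: list[str] | None = None
) -> UnconditionalResult:
    """Per-stratum ORs by ordinary logistic regression with matching-factor adjustment.

    For strata defined by variables that differ within pairs (BMI or WC
    class) the conditional likelihood cannot stratify, so a standard
    logistic model of case status on the exposure plus every matching
    factor (as dummies) is fitted within each stratum; the interaction
    p-value comes from a pooled likelihood-ratio test.
    """
    import statsmodels.api as sm

    factors = matching_factors if matching_factors is not None else cohort.matching_factors
    tab = cohort.table
    y = (tab["role"] == CASE).astype(float)
    Z = pd.get_dummies(tab[factors].astype(str), drop_first=True, dtype=float)
    xv = x.reindex(tab.index).astype(float)
    strat = stratum.reindex(tab.index)

    def _drop_collinear(design: pd.DataFrame) -> pd.DataFrame:
        A = design.to_numpy(dtype=float)
        keep: list[int] = []
        for j in range(A.shape[1]):
            if np.linalg.matrix_rank(A[:, keep + [j]]) == len(keep) + 1:
                keep.append(j)
        return design.iloc[:, keep]

    def _fit(design: pd.DataFrame, yy: pd.Series):
        design = sm.add_constant(design, has_constant="add")
        design = _drop_collinear(design)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                return sm.Logit(yy, design).fit(disp=0, maxiter=200)
            except Exception as err:  # singular information or separation
                if "ingular" in str(err) or "eparation" in str(err):
                    raise SeparationError(str(err)) from err
                raise

    rows, levels = [], []
    for lev in sorted(pd.unique(strat.dropna())):
        mask = (strat == lev).values
        if mask.sum() == 0:
            warnings.warn(f"stratum {lev!r} empty; skipped")
            continue
        yy = y[mask]
        if yy.nunique() < 2:
            raise SeparationError(f"stratum {lev!r} has only {yy.iloc[0]:.0f}-labelled subjects")
        design = pd.concat([xv[mask].rename("exposure"), Z.loc[mask]], axis=1)
        design = design.loc[:, design.nunique() > 1]
        res = _fit(design, yy)
        b, se = res.params["exposure"], res.bse["exposure"]
        rows.append(
            {
                "OR": np.exp(b),
                "ci_low": np.exp(b - _Z975 * se),
                "ci_high": np.exp(b + _Z975 * se),
                "p": res.pvalues["exposure"],
                "n": int(mask.sum()),
            }
        )
        levels.append(lev)
    # pooled interaction LRT
    keep = strat.notna().values
    strat_d = pd.get_dummies(strat[keep].astype(str), drop_first=True, dtype=float)
    base = pd.concat([xv[keep].rename("exposure"), strat_d, Z.loc[keep]], axis=1)
    inter = base.copy()
    for c in strat_d.columns:
        inter[f"exposure:{c}"] = base["exposure"] * strat_d[c]
    r0, r1 = _fit(base, y[keep]), _fit(inter, y[keep])
    lrt = max(0.0, 2.0 * (r1.llf - r0.llf))
    df = max(1, strat_d.shape[1])
    return UnconditionalResult(
        stratum.name or "stratum",
        pd.DataFrame(rows, index=levels),
        float(stats.chi2.sf(lrt, df)),
    )


# ---------------------------------------------------------------------------
# sensitivity restrictions, C-peptide standardization, covariate imputation
# ---------------------------------------------------------------------------


def restrict_pairs(cohort: MatchedCohort, predicate, apply_to: str = "both") -> MatchedCohort:
    """Keep only pairs that remain valid and complete under a restriction.

    ``predicate`` maps a covariate row (Series) to True (keep subject).
    With ``apply_to="both"`` (hormone use, fasting, diabetes) the whole pair
    is dropped if either member fails; with ``apply_to="case"`` (diagnosis
    lag) only the case is tested.  Raises if no pair survives.
    """
    tab = cohort.table
    keep_subject = tab.apply(predicate, axis=1).astype(bool)
    if apply_to == "case":
        keep_subject |= tab["role"] != CASE
    elif apply_to != "both":
        raise ValueError("apply_to must be 'both' or 'case'")
    ok_pairs = keep_subject.groupby(tab["pair_id"]).all()
    kept = ok_pairs.index[ok_pairs]
    if len(kept) == 0:
        raise ValueError("restriction removed every pair")
    out = MatchedCohort(tab[tab["pair_id"].isin(kept)].copy(), list(cohort.matching_factors))
    out.validate()
    return out


def standardize_cpeptide(values: pd.Series, phases: pd.Series) -> pd.Series:
    """z-score a biomarker within each assay phase.

    Measurements from different phases (different assays/years) are not
    comparable on the raw scale; each phase is centered and scaled by its
    own mean and sample SD.  Phases with fewer than two values or zero
    variance raise.
    """
    out = pd.Series(np.nan, index=values.index, dtype=float)
    for phase, idx in values.groupby(phases.reindex(values.index)).groups.items():
        v = values.loc[idx]
        if len(v) < 2:
            raise ValueError(f"phase {phase!r} has a single value; cannot standardize")
        sd = v.std(ddof=1)
        if sd == 0 or not np.isfinite(sd):
            raise ValueError(f"phase {phase!r} has zero variance")
        out.loc[idx] = (v - v.mean()) / sd
    return out


def impute_covariates(
    cohort: MatchedCohort,
    continuous: list[str],
    categorical: list[str],
    force_missing_category: list[str] = (),
    threshold: float = 0.05,
) -> tuple[MatchedCohort, pd.DataFrame]:
    """Median/mode covariate imputation with an explicit-missing fallback.

    Continuous variables with a missing fraction below ``threshold`` get the
    median, categorical ones the mode; categoricals at or above the
    threshold — or listed in ``force_missing_category`` (e.g. breastfeeding,
    ever-MHT) — get a ``"missing"`` level.  A continuous variable at or
    above the threshold raises (no missing level is possible without
    binning).  Returns the imputed cohort and an action report.
    """
    tab = cohort.table.copy()
    actions = []
    for col in list(continuous) + list(categorical):
        frac = float(tab[col].isna().mean())
        if frac == 0:
            actions.append((col, "none", frac))
            continue
        is_cont = col in continuous
        if col in force_missing_category or (not is_cont and frac >= threshold):
            tab[col] = tab[col].astype(object).where(tab[col].notna(), "missing")
            actions.append((col, "missing_category", frac))
        elif frac < threshold:
            if is_cont:
                tab[col] = tab[col].fillna(tab[col].median())
                actions.append((col, "median", frac))
            else:
                tab[col] = tab[col].fillna(tab[col].mode().iloc[0])
                actions.append((col, "mode", frac))
        else:
            raise ValueError(
                f"continuous covariate {col!r} is {frac:.1%} missing (>= {threshold:.0%}); "
                "bin it or list it in force_missing_category after binning"
            )
    report = pd.DataFrame(actions, columns=["covariate", "action", "missing_fraction"])
    return MatchedCohort(tab, list(cohort.matching_factors)), report
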