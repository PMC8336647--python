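"""End-to-end analysis pipeline: QC -> features -> per-metabolite models ->
minP -> clustering -> BoLasso -> heterogeneity & sensitivity.

Everything is driven by one :class:`AnalysisConfig` and a master seed that
is deterministically fanned out to every resampling stage, so re-running a
configuration reproduces every output byte for byte.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import clogit as cl
from . import features as ft
from . import multiplicity as mp
from . import qc as qcmod
from . import varclust as vc
from .bolasso import SelectionReport, bolasso as _bolasso
from .data import CASE, MatchedCohort, MetabolitePanel, PairDifferences
from .simulate import SimulationConfig, generate_cohort

__all__ = ["AnalysisConfig", "AnalysisBundle", "run_full_analysis", "summarize_cohort"]


def _default_models() -> dict[str, list[str]]:
    return {
        "crude": [],
        "bmi_adjusted": ["bmi_z"],
        "wc_adjusted": ["wc_z"],
        "cpeptide_adjusted": ["bmi_z", "cpeptide_std"],
    }


def _default_sensitivity() -> dict[str, dict]:
    return {
        "hormone_nonusers": {"column": "oc_mht_use", "op": "eq", "value": False, "apply_to": "both"},
        "fasting": {"column": "fasting_status", "op": "eq", "value": ">6h", "apply_to": "both"},
        "non_diabetic": {"column": "diabetes", "op": "eq", "value": False, "apply_to": "both"},
        "lag_gt_2y": {"column": "lag_years", "op": "gt", "value": 2.0, "apply_to": "case"},
    }


@dataclass
class AnalysisConfig:
    """Configuration of the full pipeline (model labels are data, not code)."""

    panel_prefix: str | None = None
    cohort_path: str | None = None
    simulation: SimulationConfig | None = None
    feature_definitions: str | None = None
    cv_threshold: float = 20.0
    oor_threshold: float = 0.20
    models: dict[str, list[str]] = field(default_factory=_default_models)
    heterogeneity_subgroups: list[str] = field(
        default_factory=lambda: ["menopausal_status", "fasting_status", "oc_mht_use"]
    )
    case_subgroups: list[str] = field(default_factory=lambda: ["lag_class"])
    unconditional_subgroups: list[str] = field(default_factory=lambda: ["bmi_class", "wc_class"])
    heterogeneity_features: list[str] | None = None  # None -> significant in 2nd label
    sensitivity: dict[str, dict] = field(default_factory=_default_sensitivity)
    n_clusters: int | None = None
    B_perm: int = 10_000
    B_boot: int = 100
    folds: int = 5
    selection_threshold: float = 0.90
    seed: int = 0

    @classmethod
    def from_file(cls, path: str | Path) -> "AnalysisConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text())
        if "simulation" in raw and raw["simulation"] is not None:
            sim = raw["simulation"]
            for key in ("effect_map", "bmi_metabolite_corr"):
                if key in sim:
                    sim[key] = {int(k): float(v) for k, v in sim[key].items()}
            raw["simulation"] = SimulationConfig(**sim)
        return cls(**raw)


@dataclass
class AnalysisBundle:
    """All pipeline outputs plus the run log."""

    qc_stats: qcmod.QCStats
    filter_report: qcmod.FilterReport
    analysis_matrix: pd.DataFrame
    results: dict[str, pd.DataFrame]  # model label -> per-feature OR table with perm p
    clusters: vc.ClusterSet
    selection: SelectionReport
    heterogeneity: pd.DataFrame
    sensitivity: pd.DataFrame
    cohort_summary: pd.DataFrame
    log: list[dict]

    def to_dir(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.qc_stats.to_tsv(outdir / "qc_stats.tsv")
        self.filter_report.to_tsv(outdir / "filter_report.tsv")
        self.analysis_matrix.to_csv(outdir / "analysis_matrix.tsv", sep="\t", index_label="subject_id")
        for label, tab in self.results.items():
            tab.to_csv(outdir / f"results_{label}.tsv", sep="\t", index_label="feature")
        self.clusters.assignment.rename("cluster").to_csv(
            outdir / "cluster_assignment.tsv", sep="\t", index_label="feature"
        )
        self.clusters.representatives.to_csv(
            outdir / "cluster_representatives.tsv", sep="\t", index_label="subject_id"
        )
        self.clusters.merge_history.to_csv(outdir / "cluster_merges.tsv", sep="\t", index=False)
        self.selection.to_tsv(outdir / "bolasso_selection.tsv")
        self.heterogeneity.to_csv(outdir / "heterogeneity.tsv", sep="\t", index=False)
        self.sensitivity.to_csv(outdir / "sensitivity.tsv", sep="\t", index=False)
        self.cohort_summary.to_csv(outdir / "cohort_summary.tsv", sep="\t")
        with open(outdir / "run_log.jsonl", "w") as fh:
            for rec in self.log:
                fh.write(json.dumps(rec) + "\n")


# ---------------------------------------------------------------------------


def _load_inputs(config: AnalysisConfig) -> tuple[MetabolitePanel, MatchedCohort]:
    if config.panel_prefix and config.cohort_path:
        panel = MetabolitePanel.from_tsv(config.panel_prefix)
        from .simulate import MATCHING_FACTORS

        cohort = MatchedCohort.from_tsv(config.cohort_path, list(MATCHING_FACTORS))
        return panel, cohort
    sim = config.simulation or SimulationConfig(seed=config.seed)
    panel, cohort, _ = generate_cohort(sim)
    return panel, cohort


def _prepare_covariates(cohort: MatchedCohort) -> MatchedCohort:
    """Impute covariates and add derived analysis columns (z-scores, classes)."""
    cohort, _ = cl.impute_covariates(
        cohort,
        continuous=["bmi", "wc", "cpeptide", "age_at_menarche"] if "age_at_menarche" in cohort.table else ["bmi", "wc", "cpeptide"],
        categorical=[c for c in ("smoking", "oc_ever", "mht_ever", "diabetes") if c in cohort.table],
        force_missing_category=[c for c in ("mht_ever",) if c in cohort.table],
    )
    tab = cohort.table
    tab["bmi_z"] = (tab["bmi"] - tab["bmi"].mean()) / tab["bmi"].std(ddof=1)
    tab["wc_z"] = (tab["wc"] - tab["wc"].mean()) / tab["wc"].std(ddof=1)
    if "cpeptide" in tab and "cpeptide_phase" in tab:
        tab["cpeptide_std"] = cl.standardize_cpeptide(
            np.log(tab["cpeptide"]), tab["cpeptide_phase"]
        )
    tab["bmi_class"] = pd.cut(
        tab["bmi"], [0, 18.5, 25, 30, np.inf], labels=["under", "normal", "over", "obese"]
    ).astype(str)
    tab["wc_class"] = pd.cut(tab["wc"], [0, 80, 88, np.inf], labels=["<80", "80-88", ">88"]).astype(str)
    if "lag_years" in tab:
        med = tab.loc[tab["role"] == CASE, "lag_years"].median()
        tab["lag_class"] = np.where(tab["lag_years"] > med, f">{med:.1f}y", f"<={med:.1f}y")
    return cohort


def _residualize_features(X: pd.DataFrame, covs: pd.DataFrame | None) -> pd.DataFrame:
    """Residualize standardized features on adjustment covariates, re-z-scored."""
    if covs is None or covs.shape[1] == 0:
        return X
    Z = np.column_stack([np.ones(len(X)), covs.to_numpy(dtype=float)])
    Y = X.to_numpy(dtype=float)
    coef, *_ = np.linalg.lstsq(Z, Y, rcond=None)
    R = Y - Z @ coef
    R /= R.std(axis=0, ddof=1)
    return pd.DataFrame(R, index=X.index, columns=X.columns)


def _predicate(rule: dict):
    ops = {
        "eq": lambda v, t: v == t,
        "ne": lambda v, t: v != t,
        "gt": lambda v, t: v > t,
        "ge": lambda v, t: v >= t,
        "lt": lambda v, t: v < t,
        "le": lambda v, t: v <= t,
    }
    op = ops[rule.get("op", "eq")]
    col, target = rule["column"], rule["value"]
    return lambda row: bool(op(row[col], target))


def summarize_cohort(
    cohort: MatchedCohort,
    continuous: list[str] | None = None,
    categorical: list[str] | None = None,
) -> pd.DataFrame:
    """Descriptive table by case/control role: mean (SD) or N (%)."""
    tab = cohort.table
    if continuous is None:
        continuous = [c for c in ("bmi", "wc", "cpeptide", "lag_years") if c in tab]
    if categorical is None:
        categorical = [
            c
            for c in ("menopausal_status", "fasting_status", "oc_mht_use", "smoking", "diabetes")
            if c in tab
        ]
    rows = []
    for role, grp in tab.groupby("role"):
        n_role = len(grp)
        for col in continuous:
            v = grp[col].dropna()
            if v.empty:
                warnings.warn(f"covariate {col!r} empty for {role}; omitted")
                continue
            rows.append((col, "mean (SD)", role, f"{v.mean():.2f} ({v.std(ddof=1):.2f})", len(v)))
        for col in categorical:
            v = grp[col].dropna()
            if v.empty:
                warnings.warn(f"covariate {col!r} empty for {role}; omitted")
                continue
            for lev, cnt in v.value_counts().items():
                rows.append(
                    (f"{col}={lev}", "N (%)", role, f"{cnt} ({100.0 * cnt / len(v):.1f}%)", n_role)
                )
    out = pd.DataFrame(rows, columns=["variable", "stat", "role", "value", "N"])
    return out.pivot_table(index=["variable", "stat"], columns="role", values="value", aggfunc="first")


def run_full_analysis(config: AnalysisConfig) -> AnalysisBundle:
    """Run every stage in order and return the result bundle.

    Stages: load/simulate -> QC filtering & imputation -> derived features
    -> log/z transform -> per-feature conditional logistic models for each
    adjustment label -> stepdown minP per label -> variable clustering &
    BMI-residualized representatives -> BoLasso -> heterogeneity LRTs ->
    sensitivity restrictions.  Any stage failure aborts with the stage name.
    """
    log: list[dict] = []
    ss = np.random.SeedSequence(config.seed)
    seed_perm, seed_boot = (int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(2))

    stage = "load_inputs"
    try:
        panel, cohort = _load_inputs(config)

        stage = "qc_filtering"
        qc_stats = qcmod.compute_batch_cv(panel)
        flags = qcmod.flag_measurable_range(panel)
        report = qcmod.filter_metabolites(
            panel, qc_stats, flags, cv_threshold=config.cv_threshold, oor_threshold=config.oor_threshold
        )
        for met, reason in report.excluded.items():
            log.append({"stage": stage, "excluded_metabolite": str(met), "reason": reason})
        imputed = qcmod.impute_below_range(panel, report)

        stage = "derived_features"
        defs = (
            ft.load_feature_definitions(config.feature_definitions)
            if config.feature_definitions
            else ft.default_definitions(imputed)
        )
        extended = ft.compute_features(imputed, defs) if defs else imputed

        stage = "transform_standardize"
        am = qcmod.transform_standardize(extended)

        stage = "covariates"
        cohort = _prepare_covariates(cohort)
        tab = cohort.table

        stage = "per_feature_models"
        results: dict[str, pd.DataFrame] = {}
        for label, adj in config.models.items():
            adj = [a for a in adj if a in tab.columns]
            rows = {}
            for feat in am.features:
                X = pd.concat([am.X[feat]] + [tab[a] for a in adj], axis=1)
                fit = cl.PairedConditionalLogit.from_cohort(cohort, X).fit()
                rows[feat] = fit.or_table().iloc[0]
            results[label] = pd.DataFrame(rows).T

        stage = "multiplicity"
        for i, (label, adj) in enumerate(config.models.items()):
            adj = [a for a in adj if a in tab.columns]
            Xr = _residualize_features(am.X, tab[adj] if adj else None)
            D = PairDifferences.from_cohort(cohort, Xr)
            res = mp.stepdown_minp(D, B=config.B_perm, seed=seed_perm + i, exact=False)
            results[label]["raw_perm_p"] = res.frame["raw_p"]
            results[label]["perm_p"] = res.frame["perm_p"]

        stage = "varclust"
        clusters = vc.cluster_variables(am, config.n_clusters)
        reps = vc.residualize_on_bmi(clusters.representatives, tab["bmi"])
        reps /= reps.std(axis=0, ddof=1)

        stage = "bolasso"
        Dreps = PairDifferences.from_cohort(cohort, reps)
        selection = _bolasso(
            Dreps,
            B=config.B_boot,
            folds=config.folds,
            threshold=config.selection_threshold,
            seed=seed_boot,
        )
        log.append({"stage": stage, "seed": seed_boot, "B": config.B_boot})

        stage = "heterogeneity"
        first_adj = list(config.models)[min(1, len(config.models) - 1)]
        feats = config.heterogeneity_features
        if feats is None:
            sig = results[first_adj].query("p <= 0.05").index
            feats = list(sig[:10])
        het_rows = []
        D_feat = PairDifferences.from_cohort(cohort, am.X)
        for feat in feats:
            for sub, member in [(s, "both") for s in config.heterogeneity_subgroups] + [
                (s, "case") for s in config.case_subgroups
            ]:
                if member == "case" and sub not in tab.columns:
                    continue
                labels = cl.subgroup_per_pair(cohort, sub, member=member)
                labels.name = sub
                try:
                    h = cl.lrt_heterogeneity(D_feat, feat, labels)
                except cl.SeparationError as err:
                    log.append({"stage": stage, "feature": feat, "subgroup": sub,
                                "skipped": str(err)[:120]})
                    continue
                het_rows.append({"feature": feat, "subgroup": sub, "path": "conditional",
                                 "lrt": h.lrt_stat, "df": h.df, "p": h.pvalue})
            for sub in config.unconditional_subgroups:
                if sub not in tab.columns:
                    continue
                try:
                    u = cl.fit_unconditional_adjusted(cohort, am.X[feat], tab[sub])
                except cl.SeparationError as err:
                    log.append({"stage": stage, "feature": feat, "subgroup": sub,
                                "skipped": str(err)[:120]})
                    continue
                het_rows.append({"feature": feat, "subgroup": sub, "path": "unconditional",
                                 "lrt": np.nan, "df": np.nan, "p": u.interaction_p})
        heterogeneity = pd.DataFrame(
            het_rows, columns=["feature", "subgroup", "path", "lrt", "df", "p"]
        )

        stage = "sensitivity"
        sens_rows = []
        for name, rule in config.sensitivity.items():
            if rule["column"] not in tab.columns:
                continue
            try:
                sub_cohort = cl.restrict_pairs(cohort, _predicate(rule), rule.get("apply_to", "both"))
            except ValueError as err:
                log.append({"stage": stage, "rule": name, "skipped": str(err)})
                continue
            log.append({"stage": stage, "rule": name, "n_pairs": sub_cohort.n_pairs,
                        "dropped_pairs": cohort.n_pairs - sub_cohort.n_pairs})
            for feat in feats:
                X = pd.concat([am.X[feat], tab["bmi_z"]], axis=1)
                fit = cl.PairedConditionalLogit.from_cohort(sub_cohort, X).fit()
                row = fit.or_table().iloc[0]
                sens_rows.append({"restriction": name, "feature": feat, "OR": row["OR"],
                                  "ci_low": row["ci_low"], "ci_high": row["ci_high"],
                                  "p": row["p"], "n_pairs": sub_cohort.n_pairs})
        sensitivity = pd.DataFrame(
            sens_rows, columns=["restriction", "feature", "OR", "ci_low", "ci_high", "p", "n_pairs"]
        )

        stage = "summary"
        cohort_summary = summarize_cohort(cohort)
    except Exception as err:
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {err}") from err

    log.append({"stage": "done", "seed": config.seed, "perm_seed": seed_perm, "boot_seed": seed_boot})
    return AnalysisBundle(
        qc_stats=qc_stats,
        filter_report=report,
        analysis_matrix=am.X,
        results=results,
        clusters=clusters,
        selection=selection,
        heterogeneity=heterogeneity,
        sensitivity=sensitivity,
        cohort_summary=cohort_summary,
        log=log,
    )
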