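"""Panel QC and filtering for targeted metabolomics concentration tables.

Implements the standard exclusion cascade for kit-based panels:

1. drop analytes never detected (undefined QC mean / all measurements
   missing);
2. drop analytes whose QC-replicate intra- or inter-batch coefficient of
   variation exceeds a threshold (default 20%);
3. drop analytes with more than a threshold fraction (default 20%) of
   subject observations outside the measurable range — below the LLOQ (or
   the plate-specific LOD for semi-quantitative analytes) or above the ULOQ.

Remaining below-range values are imputed at half the LLOQ (or half the
plate LOD), and the analysis matrix is formed by natural-log transform
followed by per-analyte z-scoring, so downstream odds ratios are per one SD
of log concentration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import (
    ABOVE_ULOQ,
    BELOW_LLOQ,
    BELOW_LOD,
    IN_RANGE,
    NOT_DETECTED,
    AnalysisMatrix,
    MetabolitePanel,
)

__all__ = [
    "QCStats",
    "RangeFlags",
    "FilterReport",
    "compute_batch_cv",
    "flag_measurable_range",
    "filter_metabolites",
    "impute_below_range",
    "transform_standardize",
]


@dataclass
class QCStats:
    """Per-metabolite QC coefficients of variation (percent).

    ``frame`` columns: ``intra_cv`` (median across plates of the per-plate
    replicate CV), ``inter_cv`` (CV of the plate-level QC means) and
    ``detected`` (False when the QC mean is zero or undefined).
    """

    frame: pd.DataFrame

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index_label="metabolite")


@dataclass
class RangeFlags:
    """Per-value measurable-range flags and per-metabolite summaries."""

    flags: pd.DataFrame  # subject rows x metabolites, codes from data module
    out_of_range_fraction: pd.Series


@dataclass
class FilterReport:
    """Outcome of the exclusion cascade.

    ``excluded`` maps metabolite -> reason, with precedence
    ``not_detected`` > ``cv_gt_threshold`` > ``out_of_range_gt_threshold``
    so each exclusion carries exactly one reason.
    """

    retained: list
    excluded: pd.Series  # metabolite -> reason
    out_of_range_fraction: pd.Series
    flags: pd.DataFrame

    @property
    def reason_counts(self) -> pd.Series:
        return self.excluded.value_counts()

    def to_tsv(self, path) -> None:
        status = pd.Series("retained", index=self.out_of_range_fraction.index, name="status")
        status.loc[self.excluded.index] = self.excluded
        out = pd.DataFrame(
            {"status": status, "out_of_range_fraction": self.out_of_range_fraction}
        )
        out.to_csv(path, sep="\t", index_label="metabolite")


def compute_batch_cv(panel: MetabolitePanel) -> QCStats:
    """Intra- and inter-batch CVs from the QC replicate rows.

    The intra-batch CV of a plate is ``100 * sd / mean`` over that plate's
    QC replicates (sample SD); per metabolite it is summarized as the median
    across plates.  The inter-batch CV is ``100 * sd / mean`` of the
    plate-level QC means.  Plates with fewer than two replicates are skipped
    with a warning; a zero/undefined QC mean marks the metabolite
    undetected.
    """
    qc = panel.qc_concentrations
    if qc.empty:
        raise ValueError("panel has no QC replicate rows")
    plates = panel.samples.loc[qc.index, "plate"]
    intra, plate_means = [], []
    for plate, block in qc.groupby(plates.values):
        if len(block) < 2:
            warnings.warn(f"plate {plate!r} has <2 QC replicates; skipped for intra-batch CV")
            continue
        m = block.mean(axis=0)
        s = block.std(axis=0, ddof=1)
        intra.append(100.0 * s / m)
        plate_means.append(m)
    if not intra:
        raise ValueError("no plate with >=2 QC replicates")
    intra_cv = pd.concat(intra, axis=1).median(axis=1)
    pm = pd.concat(plate_means, axis=1)
    inter_cv = 100.0 * pm.std(axis=1, ddof=1) / pm.mean(axis=1)
    grand = qc.mean(axis=0)
    detected = grand.notna() & (grand > 0)
    frame = pd.DataFrame({"intra_cv": intra_cv, "inter_cv": inter_cv, "detected": detected})
    frame.loc[~detected, ["intra_cv", "inter_cv"]] = np.nan
    return QCStats(frame.rename_axis("metabolite"))


def flag_measurable_range(panel: MetabolitePanel) -> RangeFlags:
    """Flag every subject measurement as in/below/above the measurable range.

    Fully quantitative analytes are judged against LLOQ/ULOQ; analytes with
    ``quant_type == "semi"`` against their plate-specific LOD (and ULOQ when
    present).  Missing measurements count as not detected, i.e. outside the
    range.  Fractions are over non-QC subjects only.
    """
    sub = panel.subject_concentrations
    plates = panel.samples.loc[sub.index, "plate"]
    flags = pd.DataFrame(IN_RANGE, index=sub.index, columns=sub.columns)
    for met in panel.metabolites:
        row = panel.limits.loc[met]
        vals = sub[met]
        if row["quant_type"] == "semi":
            if met not in panel.plate_lods.index:
                raise ValueError(f"semi-quantitative metabolite {met!r} has no plate LODs")
            lod = panel.plate_lods.loc[met].reindex(plates.values)
            if lod.isna().any():
                raise ValueError(f"metabolite {met!r} missing a plate LOD")
            flags.loc[vals.values < lod.values, met] = BELOW_LOD
        else:
            if not np.isfinite(row["lloq"]):
                raise ValueError(f"metabolite {met!r} has no LLOQ")
            flags.loc[vals < row["lloq"], met] = BELOW_LLOQ
        if np.isfinite(row["uloq"]):
            flags.loc[vals > row["uloq"], met] = ABOVE_ULOQ
        flags.loc[vals.isna(), met] = NOT_DETECTED
    oor = (flags != IN_RANGE).mean(axis=0).rename_axis("metabolite")
    return RangeFlags(flags, oor)


def filter_metabolites(
    panel: MetabolitePanel,
    qc: QCStats,
    range_flags: RangeFlags | None = None,
    cv_threshold: float = 20.0,
    oor_threshold: float = 0.20,
) -> FilterReport:
    """Apply the three exclusion rules and report one reason per exclusion.

    An analyte is excluded if it is undetected, else if its intra- or
    inter-batch CV is strictly above ``cv_threshold`` percent, else if its
    out-of-range fraction is strictly above ``oor_threshold``.
    """
    if range_flags is None:
        range_flags = flag_measurable_range(panel)
    sub = panel.subject_concentrations
    reasons = {}
    for met in panel.metabolites:
        row = qc.frame.loc[met]
        if not row["detected"] or sub[met].isna().all():
            reasons[met] = "not_detected"
        elif row["intra_cv"] > cv_threshold or row["inter_cv"] > cv_threshold:
            reasons[met] = "cv_gt_threshold"
        elif range_flags.out_of_range_fraction[met] > oor_threshold:
            reasons[met] = "out_of_range_gt_threshold"
    excluded = pd.Series(reasons, dtype=object)
    excluded.index.name = "metabolite"
    retained = [m for m in panel.metabolites if m not in reasons]
    return FilterReport(retained, excluded, range_flags.out_of_range_fraction, range_flags.flags)


def impute_below_range(panel: MetabolitePanel, report: FilterReport) -> MetabolitePanel:
    """Impute below-range values of retained analytes at half their limit.

    Below-LLOQ values become ``LLOQ / 2``; below-plate-LOD values become
    that plate's ``LOD / 2``.  Above-range values among retained analytes
    are unexpected under the exclusion cascade and raise.
    """
    out = panel.select(report.retained)
    sub_index = out.subject_concentrations.index
    plates = out.samples.loc[sub_index, "plate"]
    conc = out.concentrations
    for met in report.retained:
        fl = report.flags[met]
        if (fl == ABOVE_ULOQ).any():
            raise ValueError(f"retained metabolite {met!r} has above-range values")
        below_q = fl.index[fl == BELOW_LLOQ]
        if len(below_q):
            conc.loc[below_q, met] = out.limits.loc[met, "lloq"] / 2.0
        below_d = fl.index[fl == BELOW_LOD]
        if len(below_d):
            lods = out.plate_lods.loc[met].reindex(plates.loc[below_d].values)
            conc.loc[below_d, met] = lods.values / 2.0
    return out


def transform_standardize(panel: MetabolitePanel, population: str = "all") -> AnalysisMatrix:
    """Natural-log transform and z-score each analyte over analysis subjects.

    ``population`` selects whose mean/SD define the scale: ``"all"`` (cases
    and controls, the default) — a ``"controls"`` alternative can be
    realized by passing a pre-subset panel.  QC rows never enter the
    scaling.  Raises on nonpositive or missing values (imputation must run
    first) and on constant columns.
    """
    sub = panel.subject_concentrations
    vals = sub.to_numpy(dtype=float)
    if np.isnan(vals).any():
        raise ValueError("missing values present; run impute_below_range first")
    if (vals <= 0).any():
        bad = sub.columns[(vals <= 0).any(axis=0)][0]
        raise ValueError(f"nonpositive concentration in {bad!r}; cannot log-transform")
    logx = np.log(vals)
    mean = logx.mean(axis=0)
    sd = logx.std(axis=0, ddof=1)
    if (sd == 0).any():
        bad = sub.columns[sd == 0][0]
        raise ValueError(f"constant column {bad!r}; SD is zero")
    X = pd.DataFrame((logx - mean) / sd, index=sub.index, columns=sub.columns)
    return AnalysisMatrix(
        X,
        pd.Series(mean, index=sub.columns, name="log_mean"),
        pd.Series(sd, index=sub.columns, name="log_sd"),
    )
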