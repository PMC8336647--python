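"""Core data containers for matched case-control metabolomics analyses.

Two primary objects flow through the package:

* :class:`MetabolitePanel` — a subject x metabolite concentration table on
  the linear scale, together with the quantification limits (LLOQ/ULOQ for
  fully quantitative analytes, per-plate LODs for semi-quantitative ones),
  the plate assignment of every sample and the QC-replicate rows.
* :class:`MatchedCohort` — the 1:1 matched pair structure (pair id, case or
  control role), the matching strata and the subject-level covariates.

Both validate the invariants the downstream estimators rely on (complete
pairs, shared strata and plates) and round-trip to plain TSV files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

CASE = "case"
CONTROL = "control"

#: range-flag codes used across the QC module
IN_RANGE = "in_range"
BELOW_LLOQ = "below_lloq"
BELOW_LOD = "below_lod"
ABOVE_ULOQ = "above_uloq"
NOT_DETECTED = "not_detected"


class MatchingError(ValueError):
    """Raised when a valid 1:1 matched structure cannot be formed."""


@dataclass
class MetabolitePanel:
    """Subject x metabolite concentrations plus quantification metadata.

    Parameters
    ----------
    concentrations : DataFrame
        One row per sample (study subjects and QC replicates), one column per
        metabolite, linear concentration scale.  ``NaN`` encodes an
        undetected measurement.
    samples : DataFrame
        Indexed like ``concentrations``; columns ``plate`` (plate/batch id),
        ``is_qc`` (bool) and ``subject_id`` (missing for QC rows).
    limits : DataFrame
        Indexed by metabolite; columns ``lloq``, ``uloq`` and ``quant_type``
        (``"full"`` or ``"semi"``).  Semi-quantitative analytes are judged
        against per-plate LODs instead of the LLOQ.
    plate_lods : DataFrame
        metabolite x plate limits of detection (only required for
        semi-quantitative metabolites).
    """

    concentrations: pd.DataFrame
    samples: pd.DataFrame
    limits: pd.DataFrame
    plate_lods: pd.DataFrame = field(default_factory=pd.DataFrame)

    # -- accessors ---------------------------------------------------------
    @property
    def metabolites(self) -> pd.Index:
        return self.concentrations.columns

    @property
    def n_metabolites(self) -> int:
        return self.concentrations.shape[1]

    @property
    def subject_mask(self) -> pd.Series:
        return ~self.samples["is_qc"].astype(bool)

    @property
    def subject_concentrations(self) -> pd.DataFrame:
        """Concentrations of study subjects only (QC rows dropped)."""
        return self.concentrations.loc[self.subject_mask.values]

    @property
    def qc_concentrations(self) -> pd.DataFrame:
        return self.concentrations.loc[~self.subject_mask.values]

    def select(self, metabolites) -> "MetabolitePanel":
        """Return a panel restricted to the given metabolite columns."""
        metabolites = list(metabolites)
        lods = self.plate_lods
        if not lods.empty:
            lods = lods.loc[lods.index.intersection(metabolites)]
        return MetabolitePanel(
            concentrations=self.concentrations[metabolites].copy(),
            samples=self.samples.copy(),
            limits=self.limits.loc[metabolites].copy(),
            plate_lods=lods.copy(),
        )

    def validate(self) -> None:
        if not self.concentrations.index.equals(self.samples.index):
            raise ValueError("concentrations and samples must share an index")
        vals = self.concentrations.to_numpy(dtype=float)
        if np.nanmin(vals, initial=np.inf) < 0:
            raise ValueError("concentrations must be nonnegative (NaN = undetected)")
        missing = self.metabolites.difference(self.limits.index)
        if len(missing):
            raise ValueError(f"limits missing for metabolites: {list(missing)[:5]}")

    # -- IO ----------------------------------------------------------------
    def to_tsv(self, prefix: str | Path) -> None:
        prefix = Path(prefix)
        wide = pd.concat([self.samples, self.concentrations], axis=1)
        wide.to_csv(f"{prefix}.panel.tsv", sep="\t", index_label="sample_id")
        self.limits.to_csv(f"{prefix}.limits.tsv", sep="\t", index_label="metabolite")
        self.plate_lods.to_csv(f"{prefix}.plate_lods.tsv", sep="\t", index_label="metabolite")

    @classmethod
    def from_tsv(cls, prefix: str | Path) -> "MetabolitePanel":
        prefix = Path(prefix)
        wide = pd.read_csv(f"{prefix}.panel.tsv", sep="\t", index_col="sample_id")
        meta_cols = ["plate", "is_qc", "subject_id"]
        samples = wide[meta_cols].copy()
        samples["is_qc"] = samples["is_qc"].astype(bool)
        conc = wide.drop(columns=meta_cols)
        limits = pd.read_csv(f"{prefix}.limits.tsv", sep="\t", index_col="metabolite")
        lods = pd.read_csv(f"{prefix}.plate_lods.tsv", sep="\t", index_col="metabolite")
        return cls(conc, samples, limits, lods)


@dataclass
class MatchedCohort:
    """1:1 matched case-control structure with covariates.

    ``table`` is indexed by subject id and must contain ``pair_id`` and
    ``role`` (``"case"``/``"control"``) columns plus the matching-stratum
    columns named in ``matching_factors`` and any analysis covariates.
    """

    table: pd.DataFrame
    matching_factors: list[str] = field(default_factory=list)

    @property
    def pair_ids(self) -> np.ndarray:
        return np.sort(self.table["pair_id"].unique())

    @property
    def n_pairs(self) -> int:
        return self.table["pair_id"].nunique()

    def cases(self) -> pd.DataFrame:
        return self.table[self.table["role"] == CASE]

    def controls(self) -> pd.DataFrame:
        return self.table[self.table["role"] == CONTROL]

    def validate(self) -> None:
        roles = self.table.groupby("pair_id")["role"].agg(
            n="size", n_case=lambda r: (r == CASE).sum()
        )
        bad = roles[(roles["n"] != 2) | (roles["n_case"] != 1)]
        if len(bad):
            raise MatchingError(
                f"pairs without exactly one case and one control: {list(bad.index[:5])}"
            )
        for col in self.matching_factors:
            if self.table.groupby("pair_id")[col].nunique(dropna=False).max() > 1:
                raise MatchingError(f"matched members differ on matching factor {col!r}")

    def paired_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        """Return (cases, controls) aligned row-by-row on pair_id."""
        cases = self.cases().sort_values("pair_id")
        controls = self.controls().sort_values("pair_id")
        if not np.array_equal(cases["pair_id"].values, controls["pair_id"].values):
            raise MatchingError("incomplete pairs: case/control pair ids differ")
        return cases, controls

    def to_tsv(self, path: str | Path) -> None:
        out = self.table.copy()
        out.attrs = {}
        out.to_csv(path, sep="\t", index_label="subject_id")

    @classmethod
    def from_tsv(cls, path: str | Path, matching_factors: list[str] | None = None) -> "MatchedCohort":
        table = pd.read_csv(path, sep="\t", index_col="subject_id")
        return cls(table, matching_factors or [])


@dataclass
class AnalysisMatrix:
    """z-scored natural-log concentrations ready for modelling.

    ``X`` holds one row per analysis subject and one column per feature;
    every column has mean 0 and sample SD 1.  The per-feature scaling
    constants (``log_mean``, ``log_sd``) are retained so new data can be
    placed on the same scale.
    """

    X: pd.DataFrame
    log_mean: pd.Series
    log_sd: pd.Series

    @property
    def features(self) -> pd.Index:
        return self.X.columns

    def to_tsv(self, path: str | Path) -> None:
        self.X.to_csv(path, sep="\t", index_label="subject_id")


@dataclass
class PairDifferences:
    """Pair x feature matrix of case-minus-control differences.

    The 1:1 conditional logistic likelihood depends on the data only through
    these within-pair differences, so this is the canonical model input.
    """

    frame: pd.DataFrame  # index pair_id, columns features

    @property
    def values(self) -> np.ndarray:
        return self.frame.to_numpy(dtype=float)

    @property
    def feature_names(self) -> list[str]:
        return list(self.frame.columns)

    @property
    def n_pairs(self) -> int:
        return self.frame.shape[0]

    def select(self, features) -> "PairDifferences":
        return PairDifferences(self.frame[list(features)].copy())

    @classmethod
    def from_cohort(cls, cohort: MatchedCohort, X: pd.DataFrame) -> "PairDifferences":
        """Build differences from a cohort and a subject x feature matrix.

        ``X`` must be indexed by subject id (e.g. ``AnalysisMatrix.X``, or a
        covariate frame on the analysis scale).
        """
        cases, controls = cohort.paired_frames()
        xc = X.loc[cases.index].to_numpy(dtype=float)
        xk = X.loc[controls.index].to_numpy(dtype=float)
        frame = pd.DataFrame(xc - xk, index=cases["pair_id"].values, columns=X.columns)
        frame.index.name = "pair_id"
        return cls(frame)
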