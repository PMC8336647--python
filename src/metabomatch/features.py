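"""Metabolite sums and ratios computed on the concentration scale.

Carnitine-type indices (e.g. esterified-to-free carnitine, short-chain
acylcarnitines to free carnitine) are defined as sums and ratios of linear
concentrations, appended to the panel *before* the log transform and
z-scoring, so they flow through the analysis like any measured analyte.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .data import MetabolitePanel

__all__ = ["FeatureDefinition", "compute_features", "load_feature_definitions", "default_definitions"]


@dataclass
class FeatureDefinition:
    """A named sum (empty denominator) or ratio of summed concentrations."""

    name: str
    numerator: list[str]
    denominator: list[str] = field(default_factory=list)

    def validate(self, available) -> None:
        if not self.numerator:
            raise ValueError(f"feature {self.name!r}: numerator must be nonempty")
        missing = [m for m in self.numerator + self.denominator if m not in available]
        if missing:
            raise ValueError(
                f"feature {self.name!r} references metabolites not in the panel "
                f"(excluded or unknown): {missing}"
            )


# Default carnitine indices follow standard acylcarnitine chain-length
# conventions on the Biocrates-style nomenclature: C0 is free carnitine,
# esterified carnitine sums every measured acylcarnitine except C0, and
# short-chain species are the C2-C5 esters.  Fully overridable via a
# definitions file; only species present in the panel are used.
_SHORT_CHAIN = ["C2", "C3", "C3:1", "C3-OH", "C4", "C4:1", "C4-OH", "C5", "C5:1", "C5-OH", "C5:1-DC", "C5-DC", "C5-M-DC"]


def default_definitions(panel: MetabolitePanel) -> list[FeatureDefinition]:
    """Carnitine sum/ratio defaults restricted to analytes in the panel."""
    mets = set(panel.metabolites)
    acyl = [m for m in panel.metabolites if m.startswith("C") and m[1:2].isdigit() and m != "C0"]
    defs = []
    if "C0" in mets and acyl:
        defs.append(FeatureDefinition("esterified_to_free_carnitine", acyl, ["C0"]))
        short = [m for m in _SHORT_CHAIN if m in mets]
        if short:
            defs.append(FeatureDefinition("short_chain_to_free_carnitine", short, ["C0"]))
    return defs


def load_feature_definitions(path: str | Path) -> list[FeatureDefinition]:
    """Read definitions from YAML (list of name/numerator/denominator) or TSV."""
    path = Path(path)
    if path.suffix in (".yaml", ".yml"):
        import yaml

        raw = yaml.safe_load(path.read_text())
        return [
            FeatureDefinition(d["name"], list(d["numerator"]), list(d.get("denominator", []) or []))
            for d in raw
        ]
    tab = pd.read_csv(path, sep="\t")
    out = []
    for _, row in tab.iterrows():
        den = row.get("denominator", "")
        den_list = [] if pd.isna(den) or den == "" else str(den).split(",")
        out.append(FeatureDefinition(row["name"], str(row["numerator"]).split(","), den_list))
    return out


def compute_features(panel: MetabolitePanel, defs: list[FeatureDefinition]) -> MetabolitePanel:
    """Append sum/ratio columns to an imputed linear-scale panel.

    Each new column is ``sum(numerator)`` or ``sum(numerator)/sum(denominator)``
    and receives wide open limits so it passes range checks downstream.
    Zero or negative denominators raise, naming the subjects affected.
    """
    conc = panel.concentrations.copy()
    limits = panel.limits.copy()
    for d in defs:
        d.validate(panel.metabolites)
        num = conc[d.numerator].sum(axis=1)
        if d.denominator:
            den = conc[d.denominator].sum(axis=1)
            bad = den.index[(den <= 0) | den.isna()]
            # QC rows of undetected analytes may be NaN; only subjects matter
            bad = bad.intersection(conc.index[panel.subject_mask.values])
            if len(bad):
                raise ValueError(
                    f"feature {d.name!r}: nonpositive denominator for subjects {list(bad[:5])}"
                )
            vals = num / den
        else:
            vals = num
        conc[d.name] = vals
        finite = vals[np.isfinite(vals)]
        limits.loc[d.name] = {
            "lloq": float(finite.min()) / 2.0,
            "uloq": float(finite.max()) * 2.0,
            "quant_type": "full",
        }
    return MetabolitePanel(conc, panel.samples.copy(), limits, panel.plate_lods.copy())
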