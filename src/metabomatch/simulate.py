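"""Synthetic matched case-control metabolomics cohorts with known truth.

The generator emulates the data structure of a prospective nested
case-control metabolomics study on a targeted (kit-based) panel:

* block-correlated log-normal metabolite concentrations (analytes cluster
  into correlated groups, e.g. sphingomyelins or phosphatidylcholines);
* a cohort "population" from which incident cases arise through a logistic
  disease model on the standardized log-concentrations plus BMI, and 1:1
  controls are drawn at random from the same matching stratum (age band,
  center, menopausal status, fasting status, OC/MHT use at blood draw);
* plate/batch structure: matched pairs are measured on the same plate and
  every plate carries replicates of a reference plasma sample whose
  multiplicative noise hits a target coefficient of variation;
* quantification limits (LLOQ/ULOQ, per-plate LOD for semi-quantitative
  analytes) placed at configurable population quantiles;
* BMI confounding (BMI affects disease and may correlate with metabolites)
  and configurable covariate missingness.

Because the control is drawn from non-cases of the case's stratum under a
logistic disease model, the within-pair likelihood of the labels given the
two concentration vectors is exactly the 1:1 conditional logistic
likelihood, so planted per-SD log-odds effects are recovered without design
bias by the downstream estimator.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .data import MatchedCohort, MatchingError, MetabolitePanel

__all__ = ["SimulationConfig", "generate_cohort", "generate_qc_fixture", "write_dataset", "FIXTURE_SEED"]

#: packaged seed for the 188-analyte QC demonstration fixture
FIXTURE_SEED = 188_2021


def _default_block_sizes() -> list[int]:
    # 129 analytes in 64 correlated clusters: 63 pairs + one triplet
    return [2] * 63 + [3]


@dataclass
class SimulationConfig:
    """Parameters of the simulated matched-cohort world.

    Defaults mirror the study design being emulated: 853 matched pairs,
    129 retained analytes in 64 correlated clusters, 23 plates with four QC
    replicates each and a median QC CV of 7%.  Effects are per-SD log odds
    ratios on the standardized latent log-concentration scale.
    """

    n_pairs: int = 853
    n_metabolites: int = 129
    block_sizes: list[int] = field(default_factory=_default_block_sizes)
    within_block_corr: float = 0.6
    between_block_corr: float = 0.0
    effect_map: dict[int, float] = field(default_factory=dict)
    bmi_log_or: float = 0.45
    bmi_metabolite_corr: dict[int, float] = field(default_factory=dict)
    lloq_quantile: float = 0.0
    uloq_quantile: float = 1.0
    semi_quant_fraction: float = 0.0
    n_plates: int = 23
    qc_reps_per_plate: int = 4
    qc_target_cv: float = 7.0
    qc_plate_shift_cv: float = 5.0
    covariate_missing_rates: dict[str, float] = field(default_factory=dict)
    population_factor: int = 8
    disease_prevalence: float = 0.25
    n_age_bands: int = 3
    n_centers: int = 2
    seed: int = 0

    def validate(self) -> None:
        if sum(self.block_sizes) != self.n_metabolites:
            raise ValueError(
                f"block_sizes sum to {sum(self.block_sizes)}, expected {self.n_metabolites}"
            )
        if not (0 <= self.between_block_corr <= self.within_block_corr < 1):
            # factor construction requires 0 <= g <= rho < 1 for a PD covariance
            raise ValueError("need 0 <= between_block_corr <= within_block_corr < 1")
        if not (0 <= self.lloq_quantile < self.uloq_quantile <= 1):
            raise ValueError("need 0 <= lloq_quantile < uloq_quantile <= 1")
        for j in list(self.effect_map) + list(self.bmi_metabolite_corr):
            if not (0 <= int(j) < self.n_metabolites):
                raise ValueError(f"metabolite index {j} out of range")
        if self.qc_target_cv <= 0:
            raise ValueError("qc_target_cv must be positive (percent)")

    @classmethod
    def from_file(cls, path: str | Path) -> "SimulationConfig":
        path = Path(path)
        if path.suffix in (".yaml", ".yml"):
            import yaml

            raw = yaml.safe_load(path.read_text())
        elif path.suffix == ".toml":
            import tomllib

            raw = tomllib.loads(path.read_text())
        else:
            raise ValueError(f"unsupported config format: {path.suffix}")
        for key in ("effect_map", "bmi_metabolite_corr"):
            if key in raw:
                raw[key] = {int(k): float(v) for k, v in raw[key].items()}
        return cls(**raw)


def _block_index(block_sizes: list[int]) -> np.ndarray:
    return np.repeat(np.arange(len(block_sizes)), block_sizes)


def _latent_correlation(config: SimulationConfig) -> np.ndarray:
    """Metabolite x metabolite latent correlation matrix (block exchangeable)."""
    blocks = _block_index(config.block_sizes)
    same_block = blocks[:, None] == blocks[None, :]
    R = np.where(same_block, config.within_block_corr, config.between_block_corr)
    np.fill_diagonal(R, 1.0)
    return R


def _draw_latent(rng: np.random.Generator, n: int, config: SimulationConfig) -> np.ndarray:
    """Standardized latent log-concentrations with the block correlation."""
    rho, g = config.within_block_corr, config.between_block_corr
    blocks = _block_index(config.block_sizes)
    e = rng.standard_normal((n, config.n_metabolites))
    u = rng.standard_normal((n, len(config.block_sizes)))
    v = rng.standard_normal((n, 1))
    return np.sqrt(g) * v + np.sqrt(rho - g) * u[:, blocks] + np.sqrt(1.0 - rho) * e


def _draw_bmi(rng: np.random.Generator, z: np.ndarray, config: SimulationConfig) -> np.ndarray:
    """Standardized BMI with the configured metabolite correlations."""
    if not config.bmi_metabolite_corr:
        return rng.standard_normal(z.shape[0])
    c = np.zeros(config.n_metabolites)
    for j, r in config.bmi_metabolite_corr.items():
        c[int(j)] = r
    R = _latent_correlation(config)
    lam = np.linalg.solve(R, c)
    resid_var = 1.0 - float(c @ lam)
    if resid_var <= 0:
        raise ValueError("bmi_metabolite_corr incompatible with a unit-variance BMI")
    return z @ lam + np.sqrt(resid_var) * rng.standard_normal(z.shape[0])


_MENO_LEVELS = np.array(["premenopausal", "postmenopausal", "perimenopausal"])
_MENO_P = np.array([0.25, 0.60, 0.15])
_FAST_LEVELS = np.array(["0-3h", "3-6h", ">6h"])
_FAST_P = np.array([0.45, 0.18, 0.37])
_SMOKE_LEVELS = np.array(["never", "former", "smoker"])
_SMOKE_P = np.array([0.63, 0.21, 0.16])

MATCHING_FACTORS = ["age_band", "center", "menopausal_status", "fasting_status", "oc_mht_use"]


def _draw_strata(rng: np.random.Generator, n: int, config: SimulationConfig) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "age_band": rng.integers(0, config.n_age_bands, n),
            "center": rng.integers(0, config.n_centers, n),
            "menopausal_status": _MENO_LEVELS[rng.choice(3, n, p=_MENO_P)],
            "fasting_status": _FAST_LEVELS[rng.choice(3, n, p=_FAST_P)],
            "oc_mht_use": rng.random(n) < 0.20,
        }
    )


def _match_pairs(
    rng: np.random.Generator, y: np.ndarray, strata: pd.DataFrame, n_pairs: int
) -> tuple[np.ndarray, np.ndarray]:
    """Pair each sampled case with a random unused non-case from its stratum.

    Returns (case_indices, control_indices) of length n_pairs; raises
    :class:`MatchingError` naming exhausted strata if the population cannot
    supply n_pairs complete pairs.
    """
    keys = pd.MultiIndex.from_frame(strata).to_flat_index().to_numpy()
    case_idx = np.flatnonzero(y == 1)
    ctrl_idx = np.flatnonzero(y == 0)
    pools: dict = {}
    for i in ctrl_idx:
        pools.setdefault(keys[i], []).append(i)
    for pool in pools.values():
        rng.shuffle(pool)
    order = rng.permutation(case_idx)
    cases, controls, exhausted = [], [], set()
    for i in order:
        pool = pools.get(keys[i])
        if pool:
            cases.append(i)
            controls.append(pool.pop())
            if len(cases) == n_pairs:
                break
        else:
            exhausted.add(keys[i])
    if len(cases) < n_pairs:
        raise MatchingError(
            f"could only form {len(cases)}/{n_pairs} pairs; "
            f"exhausted strata (age_band, center, menopausal, fasting, oc_mht): "
            f"{sorted(exhausted)[:5]}"
        )
    return np.asarray(cases), np.asarray(controls)


def _covariates(
    rng: np.random.Generator, bmi_z: np.ndarray, role: np.ndarray
) -> pd.DataFrame:
    n = len(bmi_z)
    wc_z = 0.8 * bmi_z + 0.6 * rng.standard_normal(n)
    phase = np.where(rng.random(n) < 0.23, "phase1", "phase2")
    cpep = np.exp(
        0.35 * bmi_z + 0.4 * rng.standard_normal(n) + np.where(phase == "phase1", 0.3, 0.0)
    )
    lag = rng.gamma(shape=3.4, scale=2.44, size=n)  # mean ~8.3y, SD ~4.5y
    cov = pd.DataFrame(
        {
            "bmi": 26.0 + 4.5 * bmi_z,
            "wc": 83.0 + 11.0 * wc_z,
            "cpeptide": cpep,
            "cpeptide_phase": phase,
            "oc_ever": rng.random(n) < 0.45,
            "mht_ever": rng.random(n) < 0.38,
            "smoking": _SMOKE_LEVELS[rng.choice(3, n, p=_SMOKE_P)],
            "diabetes": rng.random(n) < 0.04,
            "lag_years": np.where(role == "case", lag, np.nan),
        }
    )
    return cov


def generate_cohort(config: SimulationConfig) -> tuple[MetabolitePanel, MatchedCohort, dict]:
    """Simulate a matched case-control metabolomics dataset with known truth.

    Returns ``(panel, cohort, truth)`` where ``truth`` records every planted
    quantity (per-SD log odds ratios, BMI effect, limits, seeds) as a
    JSON-serializable dict.  Deterministic given ``config.seed``.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    r_latent, r_strata, r_disease, r_match, r_cov, r_qc, r_miss = (
        np.random.default_rng(s) for s in ss.spawn(7)
    )

    n_pop = config.population_factor * config.n_pairs
    z = _draw_latent(r_latent, n_pop, config)
    bmi_z = _draw_bmi(r_latent, z, config)
    strata = _draw_strata(r_strata, n_pop, config)

    beta = np.zeros(config.n_metabolites)
    for j, b in config.effect_map.items():
        beta[int(j)] = b
    from scipy.special import expit, logit

    eta = logit(config.disease_prevalence) + z @ beta + config.bmi_log_or * bmi_z
    y = (r_disease.random(n_pop) < expit(eta)).astype(int)

    case_i, ctrl_i = _match_pairs(r_match, y, strata, config.n_pairs)
    sel = np.concatenate([case_i, ctrl_i])
    role = np.array(["case"] * config.n_pairs + ["control"] * config.n_pairs)
    pair_id = np.concatenate([np.arange(config.n_pairs)] * 2)

    table = strata.iloc[sel].reset_index(drop=True)
    table.insert(0, "pair_id", pair_id)
    table.insert(1, "role", role)
    table = pd.concat([table, _covariates(r_cov, bmi_z[sel], role)], axis=1)
    for col, rate in config.covariate_missing_rates.items():
        if col in MATCHING_FACTORS or col in ("pair_id", "role"):
            raise ValueError(f"cannot inject missingness into {col!r}")
        mask = r_miss.random(len(table)) < rate
        table.loc[mask, col] = np.nan
    table.index = pd.Index([f"S{i:05d}" for i in range(len(table))], name="subject_id")
    cohort = MatchedCohort(table, matching_factors=list(MATCHING_FACTORS))
    cohort.validate()

    # concentrations on the linear scale: per-analyte log-location and scale
    mu = r_latent.normal(np.log(20.0), 1.0, config.n_metabolites)
    sig = r_latent.uniform(0.35, 0.75, config.n_metabolites)
    conc = np.exp(mu + sig * z[sel])
    met_names = [f"M{j:03d}" for j in range(config.n_metabolites)]
    conc_df = pd.DataFrame(conc, index=table.index, columns=met_names)

    # matched pairs share a plate; pairs are laid out consecutively
    per_plate = int(np.ceil(config.n_pairs / config.n_plates))
    pair_plate = np.minimum(np.arange(config.n_pairs) // per_plate, config.n_plates - 1)
    plate = pair_plate[pair_id]

    # quantification limits at configured population quantiles
    if config.lloq_quantile > 0:
        lloq = np.quantile(conc, config.lloq_quantile, axis=0)
    else:
        lloq = conc.min(axis=0) / 2.0
    if config.uloq_quantile < 1:
        uloq = np.quantile(conc, config.uloq_quantile, axis=0)
    else:
        uloq = conc.max(axis=0) * 2.0
    n_semi = int(round(config.semi_quant_fraction * config.n_metabolites))
    quant_type = np.array(["semi"] * n_semi + ["full"] * (config.n_metabolites - n_semi))
    limits = pd.DataFrame(
        {"lloq": lloq, "uloq": uloq, "quant_type": quant_type},
        index=pd.Index(met_names, name="metabolite"),
    )
    plate_names = [f"P{k:02d}" for k in range(config.n_plates)]
    lod_jitter = r_qc.uniform(0.9, 1.1, (n_semi, config.n_plates))
    plate_lods = pd.DataFrame(
        lloq[:n_semi, None] * lod_jitter, index=met_names[:n_semi], columns=plate_names
    )
    plate_lods.index.name = "metabolite"

    # QC replicates: multiplicative log-normal noise around a per-plate mean
    sig_cv = np.sqrt(np.log1p((config.qc_target_cv / 100.0) ** 2))
    sig_shift = np.sqrt(np.log1p((config.qc_plate_shift_cv / 100.0) ** 2))
    shifts = r_qc.normal(0.0, sig_shift, (config.n_plates, config.n_metabolites))
    qc_rows, qc_ids, qc_plates = [], [], []
    for k in range(config.n_plates):
        noise = r_qc.normal(0.0, sig_cv, (config.qc_reps_per_plate, config.n_metabolites))
        qc_rows.append(np.exp(mu + shifts[k] + noise))
        qc_ids += [f"QC_P{k:02d}_R{r}" for r in range(config.qc_reps_per_plate)]
        qc_plates += [plate_names[k]] * config.qc_reps_per_plate
    qc_df = pd.DataFrame(np.vstack(qc_rows), index=pd.Index(qc_ids, name="subject_id"), columns=met_names)

    samples = pd.DataFrame(
        {
            "plate": np.concatenate([np.array(plate_names)[plate], qc_plates]),
            "is_qc": [False] * len(table) + [True] * len(qc_ids),
            "subject_id": list(table.index) + [""] * len(qc_ids),
        },
        index=pd.Index(list(table.index) + qc_ids, name="sample_id"),
    )
    panel = MetabolitePanel(pd.concat([conc_df, qc_df]), samples, limits, plate_lods)
    panel.validate()

    truth = {
        "seed": config.seed,
        "effect_map": {int(j): float(b) for j, b in config.effect_map.items()},
        "bmi_log_or": config.bmi_log_or,
        "bmi_metabolite_corr": {int(j): float(r) for j, r in config.bmi_metabolite_corr.items()},
        "within_block_corr": config.within_block_corr,
        "between_block_corr": config.between_block_corr,
        "block_sizes": list(config.block_sizes),
        "log_location": mu.tolist(),
        "log_scale": sig.tolist(),
        "lloq": lloq.tolist(),
        "uloq": uloq.tolist(),
        "n_pairs": config.n_pairs,
    }
    return panel, cohort, truth


# ---------------------------------------------------------------------------
# 188-analyte QC demonstration fixture
# ---------------------------------------------------------------------------

#: engineered category sizes of the fixture panel
FIXTURE_CATEGORIES = {
    "not_detected": 31,
    "high_cv": 8,
    "high_out_of_range": 20,
    "partial_below_range": 21,
    "clean": 108,
}


def _threshold_for_count(values: np.ndarray, k: int) -> float:
    """A limit strictly above exactly ``k`` of the sorted values."""
    v = np.sort(values)
    if k <= 0:
        return v[0] / 2.0
    if k >= len(v):
        return v[-1] * 2.0
    return 0.5 * (v[k - 1] + v[k])


def generate_qc_fixture(seed: int = FIXTURE_SEED) -> MetabolitePanel:
    """A 188-analyte panel exercising every panel-filtering rule.

    The panel is engineered so the standard exclusion categories occur in
    fixed numbers: 31 analytes entirely undetected, 8 with QC replicate CVs
    above 20%, 20 with more than 20% of subject observations outside the
    measurable range, 21 retained analytes with 1-20% of values below the
    LLOQ or plate LOD, and 108 fully clean — i.e. 129 analytes survive the
    three exclusion rules.  Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    n_sub, n_plates, n_reps = 100, 4, 4
    n_met = 188
    met = [f"K{j:03d}" for j in range(n_met)]
    plate_names = [f"P{k:02d}" for k in range(n_plates)]
    sub_plate = np.repeat(np.arange(n_plates), n_sub // n_plates)

    cat = np.array(
        ["not_detected"] * 31 + ["high_cv"] * 8 + ["high_oor"] * 20
        + ["partial"] * 21 + ["clean"] * 108
    )
    mu = rng.normal(np.log(20.0), 1.0, n_met)
    sig = rng.uniform(0.35, 0.75, n_met)
    conc = np.exp(mu + sig * rng.standard_normal((n_sub, n_met)))
    conc[:, cat == "not_detected"] = np.nan

    # semi-quantitative analytes judged against per-plate LODs: half of the
    # out-of-range group and a third of the partially-censored group
    semi = np.zeros(n_met, bool)
    semi[np.flatnonzero(cat == "high_oor")[::2]] = True
    semi[np.flatnonzero(cat == "partial")[::3]] = True

    lloq = np.full(n_met, np.nan)
    uloq = np.full(n_met, np.nan)
    lods = {}
    for j in range(n_met):
        col = conc[:, j]
        if cat[j] == "not_detected":
            lloq[j], uloq[j] = 1.0, 100.0
            continue
        uloq[j] = col.max() * 2.0
        frac = {"high_oor": 0.35, "partial": 0.08}.get(cat[j], 0.0)
        if semi[j]:
            lloq[j] = col.min() / 2.0  # unused for semi analytes
            per_plate = []
            for k in range(n_plates):
                vals = col[sub_plate == k]
                per_plate.append(_threshold_for_count(vals, int(round(frac * len(vals)))))
            lods[met[j]] = per_plate
        else:
            lloq[j] = _threshold_for_count(col, int(round(frac * n_sub)))

    # QC replicates: clean target CV 7%, flagged-CV analytes 50%
    cv = np.where(cat == "high_cv", 50.0, 7.0)
    sig_cv = np.sqrt(np.log1p((cv / 100.0) ** 2))
    shift_cv = np.where(cat == "high_cv", 30.0, 4.0)
    sig_shift = np.sqrt(np.log1p((shift_cv / 100.0) ** 2))
    qc_rows, qc_ids, qc_plates = [], [], []
    for k in range(n_plates):
        shift = rng.normal(0.0, sig_shift, n_met)
        noise = rng.normal(0.0, sig_cv, (n_reps, n_met))
        block = np.exp(mu + shift + noise)
        block[:, cat == "not_detected"] = np.nan
        qc_rows.append(block)
        qc_ids += [f"QC_P{k:02d}_R{r}" for r in range(n_reps)]
        qc_plates += [plate_names[k]] * n_reps

    sub_ids = [f"S{i:05d}" for i in range(n_sub)]
    conc_df = pd.DataFrame(
        np.vstack([conc] + qc_rows),
        index=pd.Index(sub_ids + qc_ids, name="sample_id"),
        columns=met,
    )
    samples = pd.DataFrame(
        {
            "plate": [plate_names[k] for k in sub_plate] + qc_plates,
            "is_qc": [False] * n_sub + [True] * len(qc_ids),
            "subject_id": sub_ids + [""] * len(qc_ids),
        },
        index=conc_df.index,
    )
    limits = pd.DataFrame(
        {"lloq": lloq, "uloq": uloq, "quant_type": np.where(semi, "semi", "full")},
        index=pd.Index(met, name="metabolite"),
    )
    plate_lods = pd.DataFrame.from_dict(lods, orient="index", columns=plate_names)
    plate_lods.index.name = "metabolite"
    return MetabolitePanel(conc_df, samples, limits, plate_lods)


def write_dataset(
    panel: MetabolitePanel, cohort: MatchedCohort, truth: dict, outdir: str | Path, stem: str = "simulated"
) -> None:
    """Write panel/cohort TSVs and the JSON truth record to ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    panel.to_tsv(outdir / stem)
    cohort.to_tsv(outdir / f"{stem}.cohort.tsv")
    (outdir / f"{stem}.truth.json").write_text(json.dumps(truth, indent=2))
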