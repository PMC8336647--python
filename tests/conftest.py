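import numpy as np
import pandas as pd
import pytest

from metabomatch import SimulationConfig, generate_cohort, generate_qc_fixture


@pytest.fixture(scope="session")
def qc_fixture_panel():
    return generate_qc_fixture()


@pytest.fixture(scope="session")
def small_dataset():
    """80 matched pairs x 6 metabolites (two triplet blocks), one planted effect."""
    cfg = SimulationConfig(
        n_pairs=80,
        n_metabolites=6,
        block_sizes=[3, 3],
        within_block_corr=0.5,
        effect_map={0: 0.4},
        bmi_log_or=0.0,
        n_plates=4,
        seed=11,
    )
    return generate_cohort(cfg)


def make_tiny_panel(qc_values_by_plate, lloq=2.0, uloq=100.0, subject_values=(5.0, 6.0)):
    """One-metabolite panel with explicit QC replicate values per plate."""
    from metabomatch.data import MetabolitePanel

    rows, ids, plates, is_qc, subj = [], [], [], [], []
    for i, v in enumerate(subject_values):
        rows.append([v])
        ids.append(f"S{i}")
        plates.append("P0")
        is_qc.append(False)
        subj.append(f"S{i}")
    for plate, vals in qc_values_by_plate.items():
        for r, v in enumerate(vals):
            rows.append([v])
            ids.append(f"QC_{plate}_R{r}")
            plates.append(plate)
            is_qc.append(True)
            subj.append("")
    conc = pd.DataFrame(np.array(rows, dtype=float), index=pd.Index(ids, name="sample_id"), columns=["met"])
    samples = pd.DataFrame({"plate": plates, "is_qc": is_qc, "subject_id": subj}, index=conc.index)
    limits = pd.DataFrame(
        {"lloq": [lloq], "uloq": [uloq], "quant_type": ["full"]},
        index=pd.Index(["met"], name="metabolite"),
    )
    return MetabolitePanel(conc, samples, limits, pd.DataFrame())


def simulate_pair_differences(rng, n_pairs, beta, corr=None):
    """Direct pair-difference simulation for estimator-level tests.

    Latent within-pair differences are N(0, 2*R); the case/control label is
    assigned with probability sigma(beta' delta), matching the conditional
    likelihood of 1:1 matched sampling under a logistic disease model.
    """
    from scipy.special import expit

    beta = np.asarray(beta, dtype=float)
    p = len(beta)
    if corr is None:
        delta = rng.standard_normal((n_pairs, p)) * np.sqrt(2.0)
    else:
        L = np.linalg.cholesky(2.0 * corr)
        delta = rng.standard_normal((n_pairs, p)) @ L.T
    sign = np.where(rng.random(n_pairs) < expit(delta @ beta), 1.0, -1.0)
    return delta * sign[:, None]
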