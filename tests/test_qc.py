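"""QC statistics, range flags, the exclusion cascade and standardization."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_tiny_panel
from metabomatch import (
    compute_batch_cv,
    filter_metabolites,
    flag_measurable_range,
    impute_below_range,
    transform_standardize,
)
from metabomatch.data import BELOW_LLOQ, BELOW_LOD, IN_RANGE, MetabolitePanel
from metabomatch.simulate import FIXTURE_CATEGORIES


class TestBatchCV:
    def test_zero_variance_replicates(self):
        panel = make_tiny_panel({"P0": [10, 10, 10, 10]})
        assert compute_batch_cv(panel).frame.loc["met", "intra_cv"] == 0.0

    def test_intra_cv_matches_sample_sd_formula(self):
        panel = make_tiny_panel({"P0": [9, 10, 11, 10]})
        # sd = sqrt(2/3), mean = 10 -> CV = 100*sqrt(2/3)/10
        expected = 100.0 * np.sqrt(2.0 / 3.0) / 10.0
        assert compute_batch_cv(panel).frame.loc["met", "intra_cv"] == pytest.approx(expected)

    def test_inter_cv_from_plate_means(self):
        panel = make_tiny_panel({"P0": [9, 9], "P1": [11, 11]})
        # plate means 9 and 11: sd = sqrt(2), mean = 10
        assert compute_batch_cv(panel).frame.loc["met", "inter_cv"] == pytest.approx(
            100.0 * np.sqrt(2.0) / 10.0
        )

    def test_single_replicate_plate_skipped_with_warning(self):
        panel = make_tiny_panel({"P0": [9, 10, 11, 10], "P1": [5]})
        with pytest.warns(UserWarning, match="<2 QC replicates"):
            stats = compute_batch_cv(panel)
        assert np.isfinite(stats.frame.loc["met", "intra_cv"])


class TestRangeFlags:
    def test_in_below_above(self):
        panel = make_tiny_panel({"P0": [10, 10]}, lloq=2.0, uloq=100.0,
                                subject_values=(5.0, 1.0, 150.0))
        fl = flag_measurable_range(panel).flags["met"]
        assert fl.loc["S0"] == IN_RANGE
        assert fl.loc["S1"] == BELOW_LLOQ
        assert fl.loc["S2"] == "above_uloq"

    def test_semi_quantitative_uses_plate_lod(self):
        panel = make_tiny_panel({"P0": [10, 10]}, subject_values=(0.5, 5.0))
        panel.limits.loc["met", "quant_type"] = "semi"
        panel.plate_lods = pd.DataFrame({"P0": [0.6]}, index=pd.Index(["met"], name="metabolite"))
        fl = flag_measurable_range(panel).flags["met"]
        assert fl.loc["S0"] == BELOW_LOD and fl.loc["S1"] == IN_RANGE

    def test_missing_limits_raise(self):
        panel = make_tiny_panel({"P0": [10, 10]})
        panel.limits.loc["met", "lloq"] = np.nan
        with pytest.raises(ValueError, match="met"):
            flag_measurable_range(panel)


class TestFilter:
    def test_exact_20pct_out_of_range_is_retained(self):
        vals = (1.0, 5.0, 5.0, 5.0, 5.0)  # exactly 20% below LLOQ=2
        panel = make_tiny_panel({"P0": [10, 10, 10]}, subject_values=vals)
        rep = filter_metabolites(panel, compute_batch_cv(panel))
        assert rep.retained == ["met"]

    def test_cv_rule_uses_intra_or_inter(self):
        # large spread within the single plate -> intra CV >> 20%
        panel = make_tiny_panel({"P0": [5, 10, 15, 20]})
        rep = filter_metabolites(panel, compute_batch_cv(panel))
        assert rep.excluded.get("met") == "cv_gt_threshold"

    def test_fixture_reason_counts(self, qc_fixture_panel):
        rep = filter_metabolites(qc_fixture_panel, compute_batch_cv(qc_fixture_panel))
        assert len(rep.retained) == 129
        counts = rep.reason_counts.to_dict()
        assert counts["not_detected"] == FIXTURE_CATEGORIES["not_detected"]
        assert counts["cv_gt_threshold"] == FIXTURE_CATEGORIES["high_cv"]
        assert counts["out_of_range_gt_threshold"] == FIXTURE_CATEGORIES["high_out_of_range"]

    def test_filter_idempotent_on_fixture(self, qc_fixture_panel):
        rep = filter_metabolites(qc_fixture_panel, compute_batch_cv(qc_fixture_panel))
        imputed = impute_below_range(qc_fixture_panel, rep)
        rep2 = filter_metabolites(imputed, compute_batch_cv(imputed))
        assert rep2.retained == rep.retained and rep2.excluded.empty

    def test_raising_lloq_never_raises_retained_count(self, qc_fixture_panel):
        stats = compute_batch_cv(qc_fixture_panel)
        base = len(filter_metabolites(qc_fixture_panel, stats).retained)
        harsher = MetabolitePanel(
            qc_fixture_panel.concentrations.copy(),
            qc_fixture_panel.samples.copy(),
            qc_fixture_panel.limits.copy(),
            qc_fixture_panel.plate_lods.copy(),
        )
        full = harsher.limits["quant_type"] == "full"
        harsher.limits.loc[full, "lloq"] *= 5.0
        assert len(filter_metabolites(harsher, stats).retained) <= base


class TestImputation:
    def test_half_lloq_and_unchanged(self):
        panel = make_tiny_panel({"P0": [10, 10]}, lloq=2.0,
                                subject_values=(1.0, 5.0, 6.0, 7.0, 8.0, 9.0))
        rep = filter_metabolites(panel, compute_batch_cv(panel))
        out = impute_below_range(panel, rep)
        assert out.concentrations.loc["S0", "met"] == 1.0  # LLOQ/2
        assert out.concentrations.loc["S1", "met"] == 5.0

    def test_half_plate_lod_for_semi(self):
        panel = make_tiny_panel({"P0": [10, 10]}, subject_values=(0.5, 5.0, 6.0, 7.0, 8.0, 9.0))
        panel.limits.loc["met", "quant_type"] = "semi"
        panel.plate_lods = pd.DataFrame({"P0": [0.6]}, index=pd.Index(["met"], name="metabolite"))
        rep = filter_metabolites(panel, compute_batch_cv(panel))
        out = impute_below_range(panel, rep)
        assert out.concentrations.loc["S0", "met"] == pytest.approx(0.3)

    def test_above_range_among_retained_raises(self):
        panel = make_tiny_panel({"P0": [10, 10]}, uloq=100.0,
                                subject_values=(150.0, 5.0, 5.0, 5.0, 5.0, 5.0))
        rep = filter_metabolites(panel, compute_batch_cv(panel))
        assert rep.retained == ["met"]  # 1/6 out of range < 20%
        with pytest.raises(ValueError, match="above-range"):
            impute_below_range(panel, rep)

    def test_imputation_never_exceeds_limit(self, qc_fixture_panel):
        rep = filter_metabolites(qc_fixture_panel, compute_batch_cv(qc_fixture_panel))
        out = impute_below_range(qc_fixture_panel, rep)
        for met in rep.retained:
            below = rep.flags.index[rep.flags[met] == BELOW_LLOQ]
            if len(below):
                assert (out.concentrations.loc[below, met] <= out.limits.loc[met, "lloq"]).all()


class TestStandardize:
    def test_hand_computed_zscores(self):
        panel = make_tiny_panel({"P0": [10, 10]},
                                subject_values=(np.e, np.e**2, np.e**3))
        am = transform_standardize(panel)
        np.testing.assert_allclose(am.X["met"].values, [-1.0, 0.0, 1.0], atol=1e-12)

    def test_columns_zero_mean_unit_sd(self, small_dataset):
        panel, _, _ = small_dataset
        am = transform_standardize(panel)
        np.testing.assert_allclose(am.X.mean(axis=0), 0.0, atol=1e-8)
        np.testing.assert_allclose(am.X.std(axis=0, ddof=1), 1.0, atol=1e-8)

    def test_constant_column_raises(self):
        panel = make_tiny_panel({"P0": [10, 10]}, subject_values=(5.0, 5.0, 5.0))
        with pytest.raises(ValueError, match="constant"):
            transform_standardize(panel)
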