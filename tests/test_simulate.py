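import numpy as np
import pandas as pd
import pytest
from dataclasses import replace
from scipy import stats

from lianameta.effects import build_effect_table
from lianameta.model import MetaRegression
from lianameta.simulate import (SimConfig, agb_config, end_to_end_recovery,
                                fit_pooled, generate_meta_dataset)
from lianameta.study_io import STUDY_COLUMNS, validate_study_table


class TestGenerator:
    def test_deterministic_under_seed(self):
        a = generate_meta_dataset(SimConfig(seed=4))
        b = generate_meta_dataset(SimConfig(seed=4))
        pd.testing.assert_frame_equal(a, b)

    def test_different_seeds_differ(self):
        a = generate_meta_dataset(SimConfig(seed=4))
        b = generate_meta_dataset(SimConfig(seed=5))
        assert not a["mean_t"].equals(b["mean_t"])

    def test_dimensions_and_schema(self, growth_table, agb_table):
        assert set(STUDY_COLUMNS) <= set(growth_table.columns)
        validate_study_table(growth_table)
        assert len(growth_table) == 103
        assert growth_table["study_id"].nunique() == 26
        assert len(agb_table) == 69
        assert agb_table["study_id"].nunique() == 12
        assert (agb_table["response_metric"] == "agb").all()

    def test_covariates_within_stated_ranges(self, growth_table):
        assert growth_table["elevation_m"].between(13, 776).all()
        assert growth_table["precip_mm_yr"].between(1144, 2964).all()
        assert growth_table["temp_c"].between(21.2, 27.7).all()
        assert growth_table["dry_season_months"].between(0, 7).all()
        assert growth_table["months_since_removal"].between(12, 228).all()

    def test_missing_fraction_binomial_bounds(self):
        cfg = SimConfig(n_studies=50, total_comparisons=1000,
                        missing_variance_fraction=0.3, seed=13)
        table = generate_meta_dataset(cfg)
        n_missing = int(table["sd_t"].isna().sum())
        # 99% binomial interval around 300 of 1000
        half = 2.576 * np.sqrt(1000 * 0.3 * 0.7)
        assert abs(n_missing - 300) <= half

    def test_null_generator_recovers_zero_mean_g(self):
        cfg = SimConfig(n_studies=50, total_comparisons=1000,
                        true_intercept=0.0, tau_study=0.0,
                        covariate_effects={}, sd_within=1.0,
                        group_n_range=(30, 60),
                        missing_variance_fraction=0.0, seed=21)
        table = generate_meta_dataset(cfg)
        eff = build_effect_table(table, "growth")
        assert abs(eff["estimate"].mean()) < 0.05

    def test_mar_missingness_targets_small_studies(self):
        cfg = SimConfig(missing_variance_fraction=0.4,
                        missing_mechanism="mar", seed=3,
                        n_studies=40, total_comparisons=400)
        table = generate_meta_dataset(cfg)
        n_tot = table["n_t"] + table["n_c"]
        miss = table["sd_t"].isna()
        assert n_tot[miss].mean() < n_tot[~miss].mean()

    def test_publication_censoring_drops_rows(self):
        cfg = SimConfig(publication_bias_strength=0.8, true_intercept=0.0,
                        covariate_effects={}, seed=6)
        table = generate_meta_dataset(cfg)
        assert len(table) < 103

    def test_impossible_config_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(n_studies=30, total_comparisons=10)
        with pytest.raises(ValueError):
            SimConfig(missing_variance_fraction=1.4)


class TestPipelineConsistency:
    def test_no_missing_data_makes_imputation_a_no_op(self, growth_table_complete):
        pooled_a, completed = fit_pooled(growth_table_complete, m=3,
                                         master_seed=1)
        eff = build_effect_table(growth_table_complete, "growth")
        direct = MetaRegression.from_dataframe(
            eff, ["months_since_removal", "n_species", "quality"]).fit()
        assert pooled_a.params["intercept"] == pytest.approx(
            direct.params["intercept"], abs=1e-12)
        for t in completed:
            assert not t["variance_was_imputed"].any()

    def test_rmse_decreases_with_study_and_plot_count(self):
        sizes = [
            dict(n_studies=13, total_comparisons=39, group_n_range=(3, 10)),
            dict(n_studies=26, total_comparisons=103, group_n_range=(8, 20)),
            dict(n_studies=52, total_comparisons=206, group_n_range=(20, 50)),
        ]
        rmses = []
        for size_kw in sizes:
            cfg = SimConfig(seed=17, covariate_effects={},
                            missing_variance_fraction=0.0, **size_kw)
            rep = end_to_end_recovery(cfg, n_replicates=30, m=1,
                                      fixed_effects=())
            rmses.append(
                float(rep.loc[rep.parameter == "intercept", "rmse"].iloc[0]))
        assert rmses[0] > rmses[1] > rmses[2]


class TestRecoveryReport:
    def test_report_structure(self):
        cfg = SimConfig(seed=2)
        rep = end_to_end_recovery(cfg, n_replicates=5, m=2)
        assert {"parameter", "truth", "bias", "rmse", "coverage"} <= \
            set(rep.columns)
        assert rep["coverage"].between(0, 1).all()
        assert "intercept" in set(rep["parameter"])

    def test_month_slope_coverage(self):
        # wide-band sanity check at 60 replicates (binomial noise ~ +/-0.07
        # around nominal); the tight calibration checks are end-to-end in
        # the acceptance tests
        cfg = SimConfig(seed=31)
        rep = end_to_end_recovery(cfg, n_replicates=60, m=2)
        cov = float(rep.loc[rep.parameter == "months_since_removal",
                            "coverage"].iloc[0])
        assert 0.85 <= cov <= 1.0
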