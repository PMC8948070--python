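import numpy as np
import pandas as pd
import pytest

from lianameta.effects import build_effect_table
from lianameta.model import (FIXED_EFFECT_SETS, MetaRegression,
                             RankDeficiencyError, build_design)
from lianameta.pooling import pool_fits


def dense_restricted_loglike(y, X, v, groups, tau2, sigma2):
    """Independent dense-matrix REML oracle (no Woodbury shortcuts)."""
    k, p = X.shape
    labels = pd.unique(groups)
    Z = np.column_stack([(groups == g).astype(float) for g in labels])
    Sigma = tau2 * Z @ Z.T + sigma2 * np.diag(v)
    Si = np.linalg.inv(Sigma)
    XtSiX = X.T @ Si @ X
    beta = np.linalg.solve(XtSiX, X.T @ Si @ y)
    r = y - X @ beta
    _, ld_S = np.linalg.slogdet(Sigma)
    _, ld_X = np.linalg.slogdet(XtSiX)
    return -0.5 * (ld_S + ld_X + r @ Si @ r + (k - p) * np.log(2 * np.pi))


class TestRemlCore:
    def test_loglike_matches_dense_oracle(self, small_effects):
        df = pd.concat([small_effects, small_effects.assign(
            comparison_id="c2", estimate=small_effects["estimate"] + 0.3)],
            ignore_index=True)
        m = MetaRegression(df["estimate"], df["variance"], df["study_id"])
        for tau2, sigma2 in [(0.01, 0.5), (0.3, 1.0), (1.2, 2.5)]:
            expected = dense_restricted_loglike(
                m.endog, m.exog, m.variances, m.groups, tau2, sigma2)
            assert m._restricted_loglike(tau2, sigma2) == \
                pytest.approx(expected, abs=1e-9)

    def test_fixed_effect_fit_equals_inverse_variance_mean(self, small_effects):
        res = MetaRegression(small_effects["estimate"],
                             small_effects["variance"],
                             small_effects["study_id"]).fit(tau2=0.0)
        y = small_effects["estimate"].to_numpy()
        v = small_effects["variance"].to_numpy()
        ivm = np.sum(y / v) / np.sum(1 / v)
        assert res.params["intercept"] == pytest.approx(ivm, abs=1e-8)

    def test_equal_variance_one_per_study_intercept_is_mean(self):
        y = np.array([0.1, 0.9, 0.4, 1.3, 0.7])
        res = MetaRegression(y, np.ones(5), np.arange(5)).fit()
        assert res.params["intercept"] == pytest.approx(y.mean(), abs=1e-8)

    def test_balanced_design_matches_oneway_anova_decomposition(self):
        # 3 studies x 2 effects, equal unit variances: REML equals the
        # classical one-way random-effects ANOVA estimators
        y = np.array([1.0, 1.4, 2.6, 3.0, 5.0, 5.6])
        g = np.array(["a", "a", "b", "b", "c", "c"])
        res = MetaRegression(y, np.ones(6), g).fit()
        means = y.reshape(3, 2).mean(axis=1)
        msw = ((y.reshape(3, 2) - means[:, None]) ** 2).sum() / 3
        msb = 2 * ((means - means.mean()) ** 2).sum() / 2
        assert res.params["intercept"] == pytest.approx(means.mean(), abs=1e-7)
        assert res.sigma2 == pytest.approx(msw, rel=1e-5)
        assert res.tau2 == pytest.approx((msb - msw) / 2, rel=1e-5)

    def test_reference_mixed_model_fit_frozen(self, growth_table_complete):
        """Full fit cross-validated against the reference weighted-LMM
        implementation (lme4 + lmerTest with Satterthwaite dfs); the
        expected numbers below were produced by that software on this
        exact table and are frozen here."""
        eff = build_effect_table(growth_table_complete, "growth")
        res = MetaRegression.from_dataframe(
            eff, ["months_since_removal", "n_species", "quality"]).fit()
        expected = {
            "intercept": (1.32801912, 0.22903723, 21.7955),
            "months_since_removal": (0.00908611, 0.00108162, 85.7889),
            "n_species": (-0.00446023, 0.00961401, 16.8777),
            "quality[medium]": (-1.05371693, 0.29005285, 20.2550),
            "quality[low]": (-1.36291676, 0.39290763, 18.7149),
        }
        for name, (est, se, df) in expected.items():
            assert res.params[name] == pytest.approx(est, abs=2e-6)
            assert res.bse[name] == pytest.approx(se, abs=2e-6)
            assert res.df[name] == pytest.approx(df, abs=0.05)
        assert res.tau2 == pytest.approx(0.291252, abs=1e-4)
        assert res.sigma2 == pytest.approx(1.189556, abs=1e-4)
        assert res.llf == pytest.approx(-126.0316, abs=1e-3)

    def test_deterministic_given_input(self, small_effects):
        df = small_effects
        r1 = MetaRegression(df["estimate"], df["variance"], df["study_id"]).fit()
        r2 = MetaRegression(df["estimate"], df["variance"], df["study_id"]).fit()
        pd.testing.assert_series_equal(r1.params, r2.params)

    def test_missing_variance_rejected(self, small_effects):
        v = small_effects["variance"].copy()
        v.iloc[0] = np.nan
        with pytest.raises(ValueError, match="variance"):
            MetaRegression(small_effects["estimate"], v,
                           small_effects["study_id"])


class TestDesignMatrix:
    def test_quality_reference_level_is_high(self, growth_table_complete):
        eff = build_effect_table(growth_table_complete, "growth")
        _, names = build_design(eff, ["quality"])
        assert "quality[high]" not in names
        assert {"quality[medium]", "quality[low]"} <= set(names)

    def test_continuous_covariates_centred(self, growth_table_complete):
        eff = build_effect_table(growth_table_complete, "growth")
        X, names = build_design(eff, ["months_since_removal"])
        assert X[:, names.index("months_since_removal")].mean() == \
            pytest.approx(0.0, abs=1e-9)

    def test_collinear_columns_named(self, growth_table_complete):
        eff = build_effect_table(growth_table_complete, "growth").copy()
        eff["months_copy"] = eff["months_since_removal"]
        with pytest.raises(RankDeficiencyError, match="months_copy"):
            build_design(eff, ["months_since_removal", "months_copy"])

    def test_objective_formulas_all_fit(self, growth_table_complete):
        eff = build_effect_table(growth_table_complete, "growth")
        for label in ("obj1", "obj2.1"):
            res = MetaRegression.from_dataframe(
                eff, FIXED_EFFECT_SETS[label]).fit()
            assert res.converged


class TestPooling:
    def _fit(self, small_effects, jitter=0.0):
        df = small_effects.copy()
        df["estimate"] = df["estimate"] + jitter
        return MetaRegression(df["estimate"], df["variance"],
                              df["study_id"]).fit()

    def test_identical_fits_pool_to_themselves(self, small_effects):
        f = self._fit(small_effects)
        pooled = pool_fits([f, f, f])
        assert pooled.params["intercept"] == pytest.approx(
            f.params["intercept"], abs=1e-12)
        assert pooled.bse["intercept"] == pytest.approx(
            f.bse["intercept"], abs=1e-12)

    def test_average_rule_is_arithmetic_mean(self, small_effects):
        f1 = self._fit(small_effects, 0.0)
        f2 = self._fit(small_effects, 1.0)
        pooled = pool_fits([f1, f2], rule="average")
        assert pooled.params["intercept"] == pytest.approx(
            (f1.params["intercept"] + f2.params["intercept"]) / 2)

    def test_rubin_rule_arithmetic(self, small_effects):
        f1 = self._fit(small_effects)
        f2 = self._fit(small_effects, 1.0)
        # overwrite to the textbook example: estimates {1,2}, SEs {0.5,0.5}
        f1.params[:] = 1.0
        f2.params[:] = 2.0
        f1.bse[:] = 0.5
        f2.bse[:] = 0.5
        pooled = pool_fits([f1, f2], rule="rubin")
        assert pooled.bse["intercept"] == pytest.approx(1.0)
        assert pooled.params["intercept"] == pytest.approx(1.5)

    def test_pooling_invariant_to_imputation_order(self, small_effects):
        fits = [self._fit(small_effects, j * 0.2) for j in range(4)]
        a = pool_fits(fits).params
        b = pool_fits(fits[::-1]).params
        pd.testing.assert_series_equal(a, b)

    def test_mismatched_coefficients_rejected(self, small_effects):
        f1 = self._fit(small_effects)
        eff = small_effects.assign(x=np.arange(6))
        f2 = MetaRegression.from_dataframe(eff, ["x"]).fit()
        with pytest.raises(ValueError, match="mismatch"):
            pool_fits([f1, f2])


class TestSummaryEffect:
    @pytest.mark.parametrize("intercept,percent,fold", [
        (1.56, 156.0, 2.56),
        (2.09, 209.0, 3.09),
        (0.0, 0.0, 1.0),
    ])
    def test_presentation_scales(self, small_effects, intercept, percent, fold):
        f = MetaRegression(small_effects["estimate"],
                           small_effects["variance"],
                           small_effects["study_id"]).fit()
        f.params[:] = intercept
        pooled = pool_fits([f])
        se = pooled.summary_effect()
        assert se["percent"] == pytest.approx(percent)
        assert se["fold"] == pytest.approx(fold)

    def test_summary_string_mentions_components(self, small_effects):
        f = MetaRegression(small_effects["estimate"],
                           small_effects["variance"],
                           small_effects["study_id"]).fit()
        s = pool_fits([f]).summary()
        assert "tau2" in s and "intercept" in s
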