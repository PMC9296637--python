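"""Calibration machinery: soil PCA, residualization as a projection,
genotype adjustment, Cook's distance against a leave-one-out oracle, and
the sequential variance partition against statsmodels anova_lm."""

import numpy as np
import pandas as pd
import pytest

from microphen import calibration, synthetic


@pytest.fixture(scope="module")
def layout():
    return synthetic.simulate_layout(
        n_blocks=4, genotypes=[f"g{i}" for i in range(6)], seed=2
    )


class TestSoilPca:
    def test_rank_one_data_concentrates_variance(self, layout, rng):
        latent = rng.normal(0, 1, len(layout))
        soil = pd.DataFrame(
            {"a": 2 * latent, "b": -latent, "c": 0.5 * latent}, index=layout.index
        )
        pcs = calibration.soil_pca(soil, k=2, standardize=False)
        assert pcs.explained_variance[0] == pytest.approx(1.0, abs=1e-12)

    def test_independent_properties_split_evenly(self, rng):
        x = rng.normal(0, 1, (5000, 3))
        soil = pd.DataFrame(x, columns=list("abc"))
        pcs = calibration.soil_pca(soil, k=3)
        np.testing.assert_allclose(pcs.explained_variance, 1 / 3, atol=0.03)

    def test_scores_orthogonal(self, layout):
        soil = synthetic.simulate_soil_field(layout, seed=9)
        pcs = calibration.soil_pca(soil, k=3)
        corr = np.corrcoef(pcs.scores.T)
        assert abs(corr[0, 1]) < 1e-8

    def test_constant_column_named_in_error(self, layout):
        soil = pd.DataFrame({"ph": 7.0, "iron": np.arange(len(layout))},
                            index=layout.index, dtype=float)
        with pytest.raises(ValueError, match="ph"):
            calibration.soil_pca(soil, k=2)


class TestCalibrateResponse:
    def test_pure_pc_signal_residuals_vanish(self, layout):
        soil = synthetic.simulate_soil_field(layout, seed=3)
        pcs = calibration.soil_pca(soil)
        y = (2.0 * pcs.scores["PC1"]).to_frame("y")
        cal = calibration.calibrate_response(y, pcs=pcs)
        assert np.abs(cal.residuals).max().max() < 1e-8

    def test_independent_values_only_centered(self, layout, rng):
        y = pd.DataFrame({"y": rng.normal(5, 1, len(layout))}, index=layout.index)
        cal = calibration.calibrate_response(y, pcs=None, coordinates=None)
        np.testing.assert_allclose(
            cal.residuals["y"], y["y"] - y["y"].mean(), atol=1e-10
        )

    def test_planted_quadratic_trend_removed(self, layout, rng):
        coords = layout[["row", "col"]]
        rs = coords["row"] / coords["row"].max()
        y = (3 * rs + 2 * rs**2 + rng.normal(0, 0.1, len(layout))).to_frame("y")
        cal = calibration.calibrate_response(y, coordinates=coords)
        # refit oracle: the trend explains <1% of residual variance
        x = np.column_stack([np.ones(len(rs)), rs, rs**2])
        coef, _, _, _ = np.linalg.lstsq(x, cal.residuals["y"], rcond=None)
        fitted = x @ coef
        assert fitted.var() < 0.01 * cal.residuals["y"].var()

    def test_calibration_is_projection(self, layout, rng):
        soil = synthetic.simulate_soil_field(layout, seed=5)
        pcs = calibration.soil_pca(soil)
        y = pd.DataFrame({"y": rng.normal(0, 1, len(layout))}, index=layout.index)
        once = calibration.calibrate_response(y, pcs=pcs, coordinates=layout[["row", "col"]])
        twice = calibration.calibrate_response(
            once.residuals, pcs=pcs, coordinates=layout[["row", "col"]]
        )
        pd.testing.assert_frame_equal(once.residuals, twice.residuals)

    def test_exp_kernel_gls_removes_trend(self, layout, rng):
        coords = layout[["row", "col"]]
        rs = coords["row"].to_numpy(float)
        y = pd.DataFrame(
            {"y": 0.5 * rs + rng.normal(0, 0.2, len(layout))}, index=layout.index
        )
        cal = calibration.calibrate_response(
            y, coordinates=coords, spatial_model="exp_kernel"
        )
        assert "kernel_range" in cal.model_record
        assert abs(np.corrcoef(cal.residuals["y"], rs)[0, 1]) < 0.9

    def test_residual_means_are_zero(self, layout, rng):
        y = pd.DataFrame({"y": rng.normal(3, 2, len(layout))}, index=layout.index)
        cal = calibration.calibrate_response(y, coordinates=layout[["row", "col"]])
        assert abs(cal.residuals["y"].mean()) < 1e-8 * y["y"].std()


class TestGenotypeAdjust:
    def test_exact_group_means_vanish(self, layout):
        g = layout["genotype"]
        y = g.map({f"g{i}": 10.0 * i for i in range(6)}).to_frame("y")
        adj = calibration.adjust_genotype(y, g)
        assert np.abs(adj.residuals).max().max() == 0

    def test_single_genotype_centers(self, rng):
        idx = [f"s{i}" for i in range(10)]
        y = pd.DataFrame({"y": rng.normal(4, 1, 10)}, index=idx)
        g = pd.Series("only", index=idx)
        adj = calibration.adjust_genotype(y, g)
        np.testing.assert_allclose(adj.residuals["y"], y["y"] - y["y"].mean())

    def test_balanced_two_groups_leave_within_variance(self, rng):
        idx = [f"s{i}" for i in range(200)]
        g = pd.Series(["a"] * 100 + ["b"] * 100, index=idx)
        within = rng.normal(0, 1.0, 200)
        y = pd.DataFrame({"y": np.where(g == "a", 10, 20) + within}, index=idx)
        adj = calibration.adjust_genotype(y, g)
        # ANOVA by hand: residual variance = pooled within-group variance
        w = np.concatenate([within[:100] - within[:100].mean(),
                            within[100:] - within[100:].mean()])
        assert adj.residuals["y"].var() == pytest.approx(np.var(w, ddof=1), rel=1e-9)

    def test_singleton_genotype_warns(self, rng):
        idx = list("abcde")
        y = pd.DataFrame({"y": rng.normal(size=5)}, index=idx)
        g = pd.Series(["x", "x", "x", "x", "lone"], index=idx)
        with pytest.warns(UserWarning, match="single observation"):
            adj = calibration.adjust_genotype(y, g)
        assert adj.residuals.loc["e", "y"] == 0


class TestCooksOutliers:
    def _design(self, n):
        return pd.DataFrame({
            "treatment": ["wet", "dry"] * (n // 2),
            "microbe": ["a"] * (n // 2) + ["b"] * (n // 2),
        }, index=[f"s{i}" for i in range(n)])

    def test_exact_fit_no_flags(self):
        design = self._design(12)
        means = {("wet", "a"): 1.0, ("dry", "a"): 2.0, ("wet", "b"): 3.0, ("dry", "b"): 4.0}
        y = pd.Series(
            [means[(t, m)] for t, m in zip(design["treatment"], design["microbe"])],
            index=design.index,
        )
        rep = calibration.cooks_outliers(y, design)
        # residuals are zero to float precision; no observation is flagged
        assert not rep.flagged.any()

    def test_single_gross_outlier_flagged_and_matches_loo_oracle(self, rng):
        n = 40
        design = self._design(n)
        y = pd.Series(rng.normal(0, 0.1, n), index=design.index)
        y.iloc[7] += 15.0
        rep = calibration.cooks_outliers(y, design)
        assert rep.flagged.iloc[7]
        assert rep.flagged.sum() <= 3
        # leave-one-out oracle: D_i from change in fitted values
        import statsmodels.api as sm

        x = calibration._interaction_design(design).to_numpy()
        full = sm.OLS(y.to_numpy(), x).fit()
        p = x.shape[1]
        s2 = full.mse_resid
        yh = full.fittedvalues
        drop = np.delete(np.arange(n), 7)
        loo = sm.OLS(y.to_numpy()[drop], x[drop]).fit()
        yh_loo = x @ loo.params
        d7 = ((yh - yh_loo) ** 2).sum() / (p * s2)
        assert rep.cooks_d.iloc[7] == pytest.approx(d7, rel=1e-6)

    def test_infinite_cutoff_flags_none(self, rng):
        design = self._design(20)
        y = pd.Series(rng.normal(size=20), index=design.index)
        rep = calibration.cooks_outliers(y, design, cutoff=np.inf)
        assert not rep.flagged.any()


class TestVariancePartition:
    def test_fully_determined_factor(self):
        f = pd.DataFrame({"a": ["x"] * 5 + ["y"] * 5}, index=range(10))
        y = pd.Series([1.0] * 5 + [9.0] * 5, index=range(10))
        vp = calibration.variance_partition(y, f)
        assert vp.set_index("term").loc["a", "proportion"] == pytest.approx(1.0)
        assert vp.set_index("term").loc["residual", "proportion"] == pytest.approx(0.0, abs=1e-12)

    def test_matches_statsmodels_sequential_anova(self, rng):
        import statsmodels.formula.api as smf
        from statsmodels.stats.anova import anova_lm

        df = pd.DataFrame({
            "a": rng.choice(["x", "y"], 60),
            "b": rng.choice(["u", "v", "w"], 60),
            "y": rng.normal(0, 1, 60),
        })
        vp = calibration.variance_partition(df["y"], df[["a", "b"]]).set_index("term")
        an = anova_lm(smf.ols("y ~ C(a) + C(b)", data=df).fit(), typ=1)
        np.testing.assert_allclose(
            vp.loc[["a", "b", "residual"], "ss"], an["sum_sq"], rtol=1e-8
        )

    def test_proportions_sum_to_one(self, rng):
        f = pd.DataFrame({"a": rng.choice(list("xy"), 30),
                          "b": rng.choice(list("uv"), 30)}, index=range(30))
        y = pd.Series(rng.normal(size=30), index=range(30))
        vp = calibration.variance_partition(y, f, interactions=True)
        assert vp["proportion"].sum() == pytest.approx(1.0, abs=1e-9)

    def test_pure_noise_factors_explain_little(self, rng):
        n = 4000
        f = pd.DataFrame({"a": rng.choice(list("xy"), n)}, index=range(n))
        y = pd.Series(rng.normal(size=n), index=range(n))
        vp = calibration.variance_partition(y, f).set_index("term")
        assert vp.loc["a", "proportion"] < 0.01
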