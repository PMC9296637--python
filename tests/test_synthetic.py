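"""Generator correctness: design balance, spatial structure, count model
limits, planted phenotype construction."""

import numpy as np
import pandas as pd
import pytest

from microphen import synthetic
from microphen.synthetic import (
    CausalOTU,
    SyntheticTruth,
    hinge_response,
    simulate_counts,
    simulate_layout,
    simulate_phenotypes,
    simulate_soil_field,
)


class TestLayout:
    def test_split_plot_design_is_balanced(self):
        layout = simulate_layout(
            n_blocks=8, genotypes=[f"G{i}" for i in range(24)], seed=1
        )
        assert len(layout) == 8 * 24 * 2 == 384
        combos = layout.groupby(["block", "watering", "genotype"]).size()
        assert (combos == 1).all()
        assert layout.index.is_unique
        assert not layout.duplicated(subset=["row", "col"]).any()
        assert (layout[["row", "col"]] >= 0).all().all()

    def test_degenerate_single_plot(self):
        layout = simulate_layout(n_blocks=1, genotypes=["g"], watering=["drought"])
        assert len(layout) == 1

    def test_same_seed_identical(self):
        a = simulate_layout(n_blocks=3, genotypes=["a", "b"], seed=42)
        b = simulate_layout(n_blocks=3, genotypes=["a", "b"], seed=42)
        pd.testing.assert_frame_equal(a, b)

    def test_grid_too_small_raises(self):
        with pytest.raises(ValueError, match="too small"):
            simulate_layout(n_blocks=4, genotypes=["a", "b"], grid_shape=(2, 2))


class TestSoil:
    def test_noiseless_linear_gradient_is_exact(self):
        layout = simulate_layout(n_blocks=4, genotypes=list("abcd"), seed=0)
        soil = simulate_soil_field(
            layout, properties=["ph", "iron"],
            gradient_params=[{"row": 2.0}], noise_sd=0.0, seed=0,
        )
        rs = layout["row"] / layout["row"].max()
        for prop in soil.columns:
            resid = np.polyfit(rs, soil[prop], 1, full=True)[1]
            assert resid[0] < 1e-18

    def test_shared_latent_drives_correlation_to_one(self):
        layout = simulate_layout(n_blocks=6, genotypes=list("abcdef"), seed=1)
        soil = simulate_soil_field(
            layout, properties=["ph", "iron"], n_latent=1, noise_sd=1e-9, seed=2
        )
        r = abs(np.corrcoef(soil["ph"], soil["iron"])[0, 1])
        assert r > 0.999999

    def test_default_field_has_positive_spatial_autocorrelation(self):
        # Moran's I with inverse-distance weights, computed directly
        layout = simulate_layout(n_blocks=6, genotypes=[f"g{i}" for i in range(8)], seed=3)
        soil = simulate_soil_field(layout, seed=4)
        xy = layout[["row", "col"]].to_numpy(float)
        d = np.hypot(*(xy[:, None, :] - xy[None, :, :]).transpose(2, 0, 1))
        w = np.where(d > 0, 1.0 / np.maximum(d, 1e-9), 0.0)
        z = soil.iloc[:, 0].to_numpy() - soil.iloc[:, 0].mean()
        n = len(z)
        moran = n / w.sum() * (z @ (w @ z)) / (z @ z)
        assert moran > 0

    def test_negative_noise_sd_raises(self):
        layout = simulate_layout(n_blocks=1, genotypes=["a"])
        with pytest.raises(ValueError):
            simulate_soil_field(layout, noise_sd=-1)


class TestHinge:
    @pytest.mark.parametrize(
        "x,tau,beta,expected",
        [(3, 5, -0.5, 0.0), (7, 5, -0.5, -1.0), (5, 5, 123.0, 0.0)],
    )
    def test_hinge_values(self, x, tau, beta, expected):
        assert hinge_response(x, tau, beta) == pytest.approx(expected)

    def test_continuous_at_threshold(self):
        eps = 1e-9
        assert hinge_response(0.3 + eps, 0.3, 2.0) == pytest.approx(0.0, abs=1e-8)


class TestCounts:
    def test_multinomial_limit_recovers_latent_proportions(self):
        layout = simulate_layout(n_blocks=8, genotypes=[f"g{i}" for i in range(16)], seed=5)
        truth = SyntheticTruth(dispersion=np.inf, zero_inflation=0.0, seed=5)
        counts, latent = simulate_counts(layout, truth, n_otus=50, seed=5)
        rel = counts.div(counts.sum(axis=1), axis=0).mean()
        expect = latent.mean()
        mc_se = np.sqrt(expect * (1 - expect) / counts.sum(axis=1).mean() / len(layout))
        assert (np.abs(rel - expect) < 3 * np.maximum(mc_se, 1e-6) + 1e-4).all()

    def test_planted_drought_enrichment_ratio(self):
        layout = simulate_layout(n_blocks=8, genotypes=[f"g{i}" for i in range(16)], seed=6)
        truth = SyntheticTruth(
            otu_treatment_effects={"OTU0001": {"watering:drought": 4.0}},
            dispersion=np.inf, zero_inflation=0.0, seed=6,
        )
        counts, _ = simulate_counts(layout, truth, n_otus=50, seed=6)
        rel = counts["OTU0001"] / counts.sum(axis=1)
        drought = layout["watering"] == "drought"
        ratio = rel[drought].mean() / rel[~drought].mean()
        assert ratio == pytest.approx(4.0, rel=0.15)

    def test_same_seed_identical_counts(self):
        layout = simulate_layout(n_blocks=2, genotypes=["a"], seed=7)
        truth = SyntheticTruth(seed=7)
        a, _ = simulate_counts(layout, truth, n_otus=20, seed=7)
        b, _ = simulate_counts(layout, truth, n_otus=20, seed=7)
        pd.testing.assert_frame_equal(a, b)

    def test_counts_are_nonneg_ints_within_depth(self):
        layout = simulate_layout(n_blocks=2, genotypes=list("ab"), seed=8)
        truth = SyntheticTruth(zero_inflation=0.0, seed=8)
        counts, _ = simulate_counts(layout, truth, n_otus=30, depth_range=(5000, 6000), seed=8)
        assert (counts >= 0).all().all()
        assert counts.to_numpy().dtype.kind == "i"
        assert counts.sum(axis=1).between(5000, 6000).all()

    def test_invalid_zero_inflation_raises(self):
        with pytest.raises(ValueError):
            SyntheticTruth(zero_inflation=1.0)


class TestPhenotypes:
    def _null_inputs(self, seed=9):
        layout = simulate_layout(n_blocks=2, genotypes=list("ab"), seed=seed)
        truth = SyntheticTruth(seed=seed)
        counts, _ = simulate_counts(layout, truth, n_otus=20, seed=seed)
        rel = counts.div(counts.sum(axis=1), axis=0)
        return layout, truth, rel

    def test_all_effects_zero_no_noise_gives_constant(self):
        layout, truth, rel = self._null_inputs()
        ph = simulate_phenotypes(layout, None, rel, truth, noise_sd=0.0)
        assert ph.nunique().eq(1).all()

    def test_noiseless_single_causal_equals_hinge(self):
        layout, truth, rel = self._null_inputs(seed=10)
        truth.causal_otus = [
            CausalOTU("OTU0003", ("area",), beta=-5.0, tau_quantile=0.4)
        ]
        ph = simulate_phenotypes(layout, None, rel, truth, noise_sd=0.0, intercept=0.0)
        c = truth.causal_otus[0]
        expect = hinge_response(rel["OTU0003"].to_numpy(), c.tau, c.beta)
        np.testing.assert_allclose(ph["area"].to_numpy(), expect, atol=1e-12)

    def test_variance_decomposition_matches_components(self):
        layout = simulate_layout(n_blocks=8, genotypes=[f"g{i}" for i in range(40)], seed=12)
        truth = SyntheticTruth(
            treatment_effects={"area": {"watering:drought": -2.0}}, seed=12
        )
        counts, _ = simulate_counts(layout, truth, n_otus=20, seed=12)
        rel = counts.div(counts.sum(axis=1), axis=0)
        noise_sd = 0.7
        ph = simulate_phenotypes(layout, None, rel, truth, noise_sd=noise_sd)
        drought = (layout["watering"] == "drought").to_numpy(float)
        expected_var = (-2.0) ** 2 * drought.var() + noise_sd**2
        assert ph["area"].var(ddof=0) == pytest.approx(expected_var, rel=0.15)

    def test_misaligned_ids_raise(self):
        layout, truth, rel = self._null_inputs()
        with pytest.raises(ValueError, match="misaligned"):
            simulate_phenotypes(layout.iloc[::-1], None, rel, truth)


def test_experiment_roundtrip_and_determinism(tmp_path):
    a = synthetic.simulate_experiment(mode="phenotyper", n_blocks=2, n_replicates=2,
                                      n_otus=40, seed=33)
    b = synthetic.simulate_experiment(mode="phenotyper", n_blocks=2, n_replicates=2,
                                      n_otus=40, seed=33)
    pd.testing.assert_frame_equal(a.counts, b.counts)
    pd.testing.assert_frame_equal(a.phenotypes, b.phenotypes)
    a.write(tmp_path, biom=True)
    truth = SyntheticTruth.from_json(tmp_path / "truth.json")
    assert [c.otu_id for c in truth.causal_otus] == [c.otu_id for c in a.truth.causal_otus]

    from microphen import _io

    biom = _io.read_biom_v1(tmp_path / "counts.biom")
    pd.testing.assert_frame_equal(
        biom, a.counts.astype(float), check_names=False
    )
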