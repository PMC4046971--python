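"""Design matrices, likelihood oracle, recovery, heteroscedastic structure."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import multivariate_normal

from ipscvar import normalization as nz
from ipscvar import synthetic_data as sd
from ipscvar import variance_components as vc


def toy_design(n_per_group=3):
    """Six samples, two donors of adult fibroblasts in one batch each."""
    rows = []
    for d, batch in [("S2", 1), ("S4", 2)]:
        for p in range(n_per_group):
            rows.append({
                "sample_id": f"fib-{d}-p{p}", "donor": d, "cell_class": "adult",
                "adult_tissue": "fibroblast", "tissue_of_origin": "none",
                "batch": batch, "replicate_label": f"p{p}",
            })
    return pd.DataFrame(rows)


class TestBuildDesign:
    def test_default_design_shapes(self, default_design):
        ds = vc.build_design(default_design)
        assert ds.z2().shape == (47, 5)
        assert (ds.blocks["origin"].sum(axis=1) > 0).sum() == 25
        assert ds.blocks["batch"].shape == (47, 2)
        # every nonzero row of every block sums to one
        for z in ds.blocks.values():
            rs = z.sum(axis=1)
            assert set(np.unique(rs)) <= {0.0, 1.0}

    def test_esc_rows_carry_no_donor_effect(self, default_design):
        ds = vc.build_design(default_design)
        esc = (default_design["cell_class"] == "ESC").to_numpy()
        assert ds.z4()[esc].sum() == 0

    def test_single_sample_design(self):
        meta = toy_design(1).iloc[[0]]
        ds = vc.build_design(meta)
        assert all(z.shape[0] == 1 for z in ds.blocks.values())

    def test_unknown_cell_class_rejected(self, default_design):
        bad = default_design.copy()
        bad.loc[0, "cell_class"] = "organoid"
        with pytest.raises(ValueError, match="cell_class"):
            vc.build_design(bad)


class TestLikelihoodOracle:
    def test_pooled_loglik_matches_dense_mvn(self, rng):
        """Brute-force check on a 6-sample toy design at random parameters."""
        design = vc.build_design(toy_design())
        y = rng.normal(0, 1, size=(7, 6))
        for _ in range(50):
            params = vc.VarianceParams(
                delta2={
                    "adult_tissue": rng.uniform(0, 2),
                    "donor_adult": rng.uniform(0, 2),
                    "batch": rng.uniform(0, 2),
                },
                residual={"all": rng.uniform(0.1, 2)},
                residual_model="homo",
            )
            ours = vc.pooled_loglik(y, design, params)
            v = vc.model_covariance(design, params)
            ref = sum(
                multivariate_normal.logpdf(y[j], mean=np.zeros(6), cov=v)
                for j in range(7)
            )
            assert ours == pytest.approx(ref, abs=1e-8)

    def test_covariance_layers_sum_to_model_covariance(self, small_study_log2fpkm, small_study):
        fit = vc.fit_mixed_model(
            small_study_log2fpkm.values, small_study["design"], n_restarts=2
        )
        layers = vc.covariance_layers(fit)
        total = sum(layers.values())
        np.testing.assert_allclose(total, fit.covariance(), atol=1e-12)
        # donor layer connects only same-donor sample pairs
        meta = small_study["metadata"]
        donor_layer = layers["donor_ipsc"]
        ipsc = (meta["cell_class"] == "iPSC").to_numpy()
        donors = meta["donor"].to_numpy()
        for a in np.flatnonzero(ipsc)[:5]:
            for b in np.flatnonzero(ipsc)[:5]:
                if a != b and donors[a] != donors[b]:
                    assert donor_layer[a, b] == 0.0

    def test_zero_variance_component_gives_zero_layer(self, small_study, small_study_log2fpkm):
        fit = vc.fit_mixed_model(
            small_study_log2fpkm.values, small_study["design"],
            components=["donor_ipsc"], n_restarts=2,
        )
        full_layers = vc.covariance_layers(fit)
        assert np.all(full_layers["batch"] == 0.0)


class TestVarianceExplained:
    @pytest.mark.parametrize("d2, s2, expected", [(1.0, 1.0, 0.5), (0.0, 1.0, 0.0), (3.0, 1.0, 0.75)])
    def test_intraclass_correlation_formula(self, default_design, d2, s2, expected):
        ds = vc.build_design(default_design)
        params = vc.VarianceParams(
            delta2={c: d2 for c in vc.COMPONENTS},
            residual={"all": s2},
            residual_model="homo",
        )
        assert vc.variance_explained(params, ds, "donor_ipsc") == pytest.approx(expected)


class TestFitRecovery:
    def test_donor_ve_recovered_in_panel_regime(self, small_study, small_study_log2fpkm):
        fit = vc.fit_mixed_model(small_study_log2fpkm.values, small_study["design"])
        assert fit.ve["donor_ipsc"] == pytest.approx(0.38, abs=0.05)
        assert fit.ve["donor_adult"] == pytest.approx(0.42, abs=0.07)

    def test_null_simulation_recovers_zeros(self):
        params = vc.VarianceParams(
            delta2={c: 0.0 for c in vc.COMPONENTS},
            residual={"all": 1.0}, residual_model="homo",
        )
        study = sd.simulate_study(sd.SimulationConfig(
            n_genes=2000, variance_params=params, seed=21))
        l2 = nz.log_transform(nz.compute_fpkm(study["counts"]))
        fit = vc.fit_mixed_model(l2.values, study["design"])
        assert all(v < 0.02 for v in fit.params.delta2.values())

    def test_adding_component_never_decreases_loglik(self, small_study, small_study_log2fpkm):
        y, design = small_study_log2fpkm.values, small_study["design"]
        sub = vc.fit_mixed_model(y, design, components=["donor_ipsc", "batch"])
        full = vc.fit_mixed_model(
            y, design, components=["donor_ipsc", "batch", "adult_tissue"]
        )
        assert full.params.loglik >= sub.params.loglik - 1e-6

    def test_dropping_null_component_leaves_others_stable(self, small_study, small_study_log2fpkm):
        # batch truth is tiny; dropping it must not move the other VEs much
        out = vc.refit_excluding(
            small_study_log2fpkm.values, small_study["design"], "batch"
        )
        for c in ("donor_ipsc", "origin", "adult_tissue"):
            assert abs(out["ve_with"][c] - out["ve_without"][c]) < 0.01

    def test_batch_free_simulation_batch_drop_loglik_flat(self):
        params = sd.default_variance_params()
        params.delta2["batch"] = 0.0
        study = sd.simulate_study(sd.SimulationConfig(
            n_genes=500, variance_params=params, seed=30))
        l2 = nz.log_transform(nz.compute_fpkm(study["counts"]))
        out = vc.refit_excluding(l2.values, study["design"], "batch")
        assert abs(out["with"].params.loglik - out["without"].params.loglik) < 1.0


class TestHeteroscedastic:
    def test_het1_recovers_residual_ratio(self):
        params = sd.default_variance_params("het1")
        params.residual = {"adult": 1.0, "iPSC": 0.5, "ESC": 1.0}
        study = sd.simulate_study(sd.SimulationConfig(
            n_genes=2000, variance_params=params, seed=23))
        l2 = nz.log_transform(nz.compute_fpkm(study["counts"]))
        fit = vc.fit_mixed_model(l2.values, study["design"], residual_model="het1")
        ratio = fit.params.residual["iPSC"] / fit.params.residual["adult"]
        assert ratio == pytest.approx(0.5, rel=0.2)

    def test_model2_constrained_equal_reduces_to_model1(self, small_study, small_study_log2fpkm):
        y, design = small_study_log2fpkm.values, small_study["design"]
        fit1 = vc.fit_mixed_model(y, design, residual_model="het1")
        r = fit1.params.residual
        mapped = vc.VarianceParams(
            delta2=dict(fit1.params.delta2),
            residual={
                "F-adult": r["adult"], "K-adult": r["adult"], "E-adult": r["adult"],
                "F-iPSC": r["iPSC"], "K-iPSC": r["iPSC"], "E-iPSC": r["iPSC"],
                "ESC": r["ESC"],
            },
            residual_model="het2",
        )
        ll2 = vc.profiled_loglik(y, design, mapped)
        assert ll2 == pytest.approx(fit1.params.loglik, abs=1e-6)


class TestConfounding:
    def test_dropping_donor_inflates_origin_ve(self):
        meta = sd.confounded_ipsc_design()
        params = sd.default_variance_params()
        params.delta2["origin"] = 0.0
        study = sd.simulate_study(sd.SimulationConfig(
            n_genes=1500, design=meta, variance_params=params, seed=24))
        l2 = nz.log_transform(nz.compute_fpkm(study["counts"]))
        design = study["design"]
        full = vc.fit_mixed_model(l2.values, design,
                                  components=["origin", "donor_ipsc", "batch"])
        reduced = vc.fit_mixed_model(l2.values, design,
                                     components=["origin", "batch"])
        assert reduced.ve["origin"] > full.ve["origin"] + 0.05


class TestDegenerateInput:
    def test_zero_variance_genes_dropped(self, small_study, small_study_log2fpkm):
        y = small_study_log2fpkm.values.copy().astype(float)
        y[:5] = 3.0  # constant rows
        fit = vc.fit_mixed_model(y, small_study["design"], n_restarts=2)
        assert fit.n_genes == y.shape[0] - 5

    def test_all_constant_matrix_raises(self, small_study):
        y = np.full((10, 47), 2.0)
        with pytest.raises(ValueError, match="variance"):
            vc.fit_mixed_model(y, small_study["design"])
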