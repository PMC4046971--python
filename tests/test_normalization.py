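"""FPKM arithmetic, GC correction, mixture EM, clustering, precision."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ipscvar import normalization as nz
from ipscvar import synthetic_data as sd
from ipscvar.io_formats import ExpressionMatrix


def _counts(values, lengths=None, libs=None):
    values = np.asarray(values)
    g, s = values.shape
    return ExpressionMatrix(
        [f"g{i}" for i in range(g)], [f"s{i}" for i in range(s)],
        values, "counts",
        gene_lengths=lengths if lengths is not None else np.full(g, 1000.0),
        library_sizes=libs if libs is not None else np.full(s, 1e6),
    )


class TestFpkm:
    def test_unit_definition(self):
        # 1,000 fragments on a 1 kb gene in a 1 M library -> FPKM 1,000
        m = nz.compute_fpkm(_counts([[1000]]))
        assert m.values[0, 0] == pytest.approx(1000.0)

    def test_zero_fragments_zero_fpkm(self):
        assert nz.compute_fpkm(_counts([[0]])).values[0, 0] == 0.0

    def test_doubling_library_size_halves_fpkm(self):
        a = nz.compute_fpkm(_counts([[100]], libs=np.array([1e6])))
        b = nz.compute_fpkm(_counts([[100]], libs=np.array([2e6])))
        assert b.values[0, 0] == pytest.approx(a.values[0, 0] / 2)

    @settings(max_examples=25, deadline=None)
    @given(
        scale=st.integers(min_value=2, max_value=7),
        seed=st.integers(min_value=0, max_value=10_000),
    )
    def test_linear_in_counts_inverse_linear_in_libsize(self, scale, seed):
        rng = np.random.default_rng(seed)
        vals = rng.integers(0, 500, size=(4, 3))
        libs = rng.uniform(1e6, 5e7, size=3)
        base = nz.compute_fpkm(_counts(vals, libs=libs)).values
        scaled = nz.compute_fpkm(_counts(vals * scale, libs=libs)).values
        np.testing.assert_allclose(scaled, base * scale, rtol=1e-12)
        lib_scaled = nz.compute_fpkm(_counts(vals, libs=libs * scale)).values
        np.testing.assert_allclose(lib_scaled, base / scale, rtol=1e-12)

    def test_zero_length_errors(self):
        with pytest.raises(ValueError, match="length"):
            nz.compute_fpkm(_counts([[1]], lengths=np.array([0.0])))

    @pytest.mark.parametrize("fpkm, pc, expected", [(1.0, 1.0, 1.0), (0.0, 1.0, 0.0), (3.0, 1.0, 2.0)])
    def test_log_transform_values(self, fpkm, pc, expected):
        m = ExpressionMatrix(["g"], ["s"], np.array([[fpkm]]), "fpkm")
        assert nz.log_transform(m, pc).values[0, 0] == pytest.approx(expected)


class TestGCCorrection:
    def test_unbiased_sample_profile_near_one(self, rng):
        g = 10000
        gc = rng.uniform(0.3, 0.7, g)
        vals = rng.poisson(200, size=(g, 3))
        _, prof = nz.gc_correction(_counts(vals), gc)
        assert prof.enrichment.min() > 0.95 and prof.enrichment.max() < 1.05

    def test_synthetic_bias_corrected_flat(self, rng):
        g = 10000
        gc = rng.uniform(0.3, 0.7, g)
        base = rng.poisson(200, size=(g, 4)).astype(float)
        biased = base.copy()
        biased[:, 0] = np.round(base[:, 0] * (1 + gc))
        corrected, prof = nz.gc_correction(_counts(biased), gc)
        # biased sample's fitted enrichment increases with GC
        lo = prof.predict(0, np.array([0.35]))[0]
        hi = prof.predict(0, np.array([0.65]))[0]
        assert hi > lo
        m2 = ExpressionMatrix(
            corrected.gene_ids, corrected.sample_ids, corrected.values, "fpkm"
        )
        _, prof2 = nz.gc_correction(m2, gc)
        assert np.abs(np.log2(prof2.enrichment)).max() < 0.1

    def test_idempotent_on_corrected_data(self, rng):
        g = 5000
        gc = rng.uniform(0.3, 0.7, g)
        vals = np.round(rng.poisson(300, size=(g, 3)) * (1 + gc[:, None]))
        corrected, _ = nz.gc_correction(_counts(vals), gc)
        m2 = ExpressionMatrix(corrected.gene_ids, corrected.sample_ids, corrected.values, "fpkm")
        twice, _ = nz.gc_correction(m2, gc)
        rel = np.abs(twice.values - corrected.values) / np.maximum(corrected.values, 1)
        assert rel.max() < 0.01

    def test_single_bin_is_global_scalar(self, rng):
        g = 200
        gc = rng.uniform(0.4, 0.6, g)
        vals = rng.poisson(100, size=(g, 2))
        corrected, _ = nz.gc_correction(_counts(vals), gc, n_bins=1)
        ratio = corrected.values / np.maximum(vals, 1e-12)
        for i in range(2):
            col = ratio[vals[:, i] > 0, i]
            np.testing.assert_allclose(col, col[0], rtol=1e-9)

    def test_gc_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="GC"):
            nz.gc_correction(_counts([[1], [2]]), np.array([0.5, 1.0]))


class TestExpressionModeMixture:
    def test_two_mode_recovery(self, rng):
        x = np.concatenate([rng.normal(0, 0.3, 2500), rng.normal(3, 0.3, 2500)])
        truth = np.arange(5000) >= 2500
        fit = nz.expression_mode_mixture(x)
        assert fit.means[0] == pytest.approx(0.0, abs=0.05)
        assert fit.means[1] == pytest.approx(3.0, abs=0.05)
        assigned_active = fit.posterior_repressed < 0.5
        assert (assigned_active == truth).mean() > 0.99

    def test_symmetric_single_gaussian_finds_no_modes(self, rng):
        # unimodal symmetric data: the fitted component means must collapse
        # together (no spurious bimodality) and points at the center must
        # not receive a confident mode assignment
        z = rng.normal(0, 1, 2000)
        x = np.concatenate([z, -z])
        fit = nz.expression_mode_mixture(x)
        assert abs(fit.means[1] - fit.means[0]) < 0.1
        near_center = np.abs(x) < 0.05
        p = fit.posterior_repressed[near_center].mean()
        assert 0.05 < p < 0.95

    def test_extreme_low_tail_is_repressed(self, rng):
        x = np.concatenate([rng.normal(0, 0.3, 1000), rng.normal(3, 0.3, 1000), [-8.0]])
        fit = nz.expression_mode_mixture(x)
        assert fit.posterior_repressed[-1] > 0.999

    def test_degenerate_input_errors(self):
        with pytest.raises(ValueError, match="no mixture"):
            nz.expression_mode_mixture(np.full(100, 2.0))


class TestCorrelationClustering:
    def test_duplicate_sample_is_adjacent_with_r_one(self, rng):
        vals = rng.normal(5, 2, size=(500, 4))
        vals = np.column_stack([vals, vals[:, 0]])
        m = ExpressionMatrix([f"g{i}" for i in range(500)],
                             ["a", "b", "c", "d", "a_dup"], vals, "log2fpkm")
        corr, order = nz.correlation_heatmap_order(m)
        assert corr.loc["a", "a_dup"] == pytest.approx(1.0)
        assert abs(order.index("a") - order.index("a_dup")) == 1

    def test_independent_samples_low_offdiagonal(self, rng):
        vals = rng.normal(0, 1, size=(5000, 6))
        m = ExpressionMatrix([f"g{i}" for i in range(5000)],
                             [f"s{i}" for i in range(6)], vals, "log2fpkm")
        corr, _ = nz.correlation_heatmap_order(m)
        off = corr.to_numpy()[~np.eye(6, dtype=bool)]
        assert np.abs(off).max() < 0.05

    def test_donor_blocks_cluster_together(self):
        # donor variance only: same-donor samples must correlate more
        study = sd.simulate_study(sd.SimulationConfig(
            n_genes=2000, seed=42,
            variance_params=sd.VarianceParams(
                delta2={"adult_tissue": 0.0, "pluripotent": 0.0, "origin": 0.0,
                        "donor_adult": 2.0, "donor_ipsc": 2.0, "batch": 0.0},
                residual={"all": 1.0}, residual_model="homo"),
        ))
        from ipscvar import normalization
        l2 = normalization.log_transform(normalization.compute_fpkm(study["counts"]))
        corr, _ = nz.correlation_heatmap_order(l2)
        meta = study["metadata"].set_index("sample_id")
        ipsc = [s for s in corr.index if meta.loc[s, "cell_class"] == "iPSC"]
        same, diff = [], []
        for i, a in enumerate(ipsc):
            for b in ipsc[i + 1:]:
                (same if meta.loc[a, "donor"] == meta.loc[b, "donor"] else diff).append(
                    corr.loc[a, b]
                )
        assert np.mean(same) > np.mean(diff)


class TestGenePrecision:
    def test_known_within_group_variance(self):
        # two groups of two replicates, pooled within-group variance 0.25 -> tau 4
        d = np.sqrt(0.5)  # |pair difference| giving per-pair variance 0.25
        y = np.array([[0.0, d, 5.0, 5.0 + d]])
        groups = np.array(["a", "a", "b", "b"])
        gp = nz.gene_precision(y, groups)
        assert gp.tau[0] == pytest.approx(4.0)

    def test_constant_gene_capped(self, rng):
        y = np.vstack([rng.normal(0, 1, 6), np.full(6, 3.0)])
        gp = nz.gene_precision(y, np.array(["a"] * 3 + ["b"] * 3))
        assert gp.tau[1] == gp.cap and gp.n_capped >= 1

    def test_rank_correlation_with_true_precision(self, rng):
        g, reps = 2000, 5
        true_sd = rng.uniform(0.2, 2.0, g)
        y = rng.normal(0, 1, size=(g, reps)) * true_sd[:, None]
        gp = nz.gene_precision(y, np.zeros(reps, dtype=int))
        from scipy.stats import spearmanr
        rho = spearmanr(gp.tau, 1.0 / true_sd**2).statistic
        assert rho > 0.8


class TestFilterTopExpressed:
    def test_zero_percentile_is_identity(self, rng):
        m = _counts(rng.integers(0, 100, size=(50, 3)))
        out = nz.filter_top_expressed(m, 0)
        np.testing.assert_array_equal(out.values, m.values)

    def test_removes_exactly_top_percentile(self, rng):
        vals = rng.integers(0, 1000, size=(100, 4))
        m = _counts(vals)
        out = nz.filter_top_expressed(m, 1)
        assert len(out.gene_ids) == 99
        # oracle: the removed gene is the top-1 by mean
        means = vals.mean(axis=1)
        removed = set(m.gene_ids) - set(out.gene_ids)
        assert removed == {m.gene_ids[int(np.argmax(means))]}
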