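"""NB five-hypothesis classifier, permutation FDR, proportions, isoforms."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ipscvar import diff_expression as de
from ipscvar import synthetic_data as sd


@pytest.fixture(scope="module")
def null_triple():
    sim = sd.simulate_three_way_counts(4000, de_proportions={"IE": 1.0}, seed=50)
    y, lab = sim["counts"].values, sim["class_labels"]
    sf = de.size_factors(y)
    alpha = de.estimate_dispersions(y, lab, sf).alpha
    return y, lab, sf, alpha


@pytest.fixture(scope="module")
def planted_triple():
    sim = sd.simulate_three_way_counts(
        1500,
        de_proportions={"IE": 0.7, "CR": 0.1, "TM": 0.1, "AR": 0.1},
        effect_log2fc=2.0,
        seed=51,
    )
    y, lab = sim["counts"].values, sim["class_labels"]
    sf = de.size_factors(y)
    alpha = de.estimate_dispersions(y, lab, sf).alpha
    cls = de.classify_genes(y, lab, sf, alpha, p_threshold=1e-3)
    return sim, y, lab, sf, alpha, cls


class TestSizeFactorsAndDispersion:
    def test_size_factors_recover_known_scaling(self, rng):
        base = rng.poisson(100, size=(2000, 4)).astype(float)
        scale = np.array([0.5, 1.0, 1.5, 2.0])
        sf = de.size_factors(np.round(base * scale))
        np.testing.assert_allclose(sf / sf.mean(), scale / scale.mean(), rtol=0.05)

    def test_poisson_counts_give_near_zero_trend_intercept(self):
        sim = sd.simulate_three_way_counts(
            5000, de_proportions={"IE": 1.0}, dispersion_trend=(0.0, 1e-9), seed=52
        )
        fit = de.estimate_dispersions(sim["counts"].values, sim["class_labels"])
        assert fit.trend[1] < 0.01

    def test_nb_trend_slope_recovered(self):
        sim = sd.simulate_three_way_counts(
            5000, de_proportions={"IE": 1.0}, dispersion_trend=(2.0, 0.1), seed=53
        )
        fit = de.estimate_dispersions(sim["counts"].values, sim["class_labels"])
        assert 0.07 < fit.trend[1] < 0.13

    def test_all_zero_gene_excluded(self, rng):
        y = rng.poisson(50, size=(10, 19))
        y[3] = 0
        labels = np.array(["adult"] * 6 + ["iPSC"] * 9 + ["ESC"] * 4)
        fit = de.estimate_dispersions(y, labels)
        assert not fit.kept[3] and fit.kept.sum() == 9


class TestLikelihoodOracle:
    def test_nb_loglik_matches_scipy_pmf_sum(self, rng):
        """Fitted-parameter likelihoods equal brute-force pmf summation."""
        for _ in range(100):
            n = int(rng.integers(4, 12))
            alpha = float(rng.uniform(0.01, 0.5))
            q = float(rng.uniform(5, 500))
            sf = rng.uniform(0.5, 2.0, n)
            mu = q * sf
            y = rng.poisson(mu)[None, :].astype(float)
            ours = de.nb_loglik(y, mu[None, :], np.array([alpha]))[0]
            r = 1.0 / alpha
            p = r / (r + mu)
            ref = stats.nbinom.logpmf(y[0], r, p).sum()
            assert ours == pytest.approx(ref, abs=1e-8)

    def test_fit_nb_mean_is_ml_optimum(self, rng):
        y = rng.poisson(80, size=(50, 10)).astype(float)
        sf = rng.uniform(0.7, 1.4, 10)
        alpha = np.full(50, 0.05)
        q, ll, _ = de.fit_nb_mean(y, sf, alpha)
        for delta in (0.99, 1.01):
            ll_shift = de.nb_loglik(y, (q * delta)[:, None] * sf[None, :], alpha)
            assert np.all(ll >= ll_shift - 1e-10)


class TestClassification:
    def test_hypothesis_nesting_invariant(self, planted_triple):
        _, _, _, _, _, cls = planted_triple
        alt_max = cls[["loglik_CR", "loglik_TM", "loglik_AR"]].max(axis=1)
        assert (cls["loglik_CX"] >= alt_max - 1e-6).all()
        assert (alt_max >= cls["loglik_H0"] - 1e-6).all()

    def test_null_p_values_uniform(self, null_triple):
        y, lab, sf, alpha = null_triple
        cls = de.classify_genes(y, lab, sf, alpha)
        for h in ("CR", "TM", "AR", "CX"):
            assert stats.kstest(cls[f"p_{h}"], "uniform").pvalue > 0.01

    def test_planted_categories_recovered(self, planted_triple):
        sim, _, _, _, _, cls = planted_triple
        truth = sim["truth"]
        for cat in ("CR", "TM", "AR"):
            sel = (truth["category"] == cat).to_numpy()
            assert (cls.loc[sel, "category"] == cat).mean() >= 0.95

    def test_exactly_equal_counts_give_zero_lr(self):
        y = np.tile([[100]], (3, 19)).astype(float)
        labels = np.array(["adult"] * 6 + ["iPSC"] * 9 + ["ESC"] * 4)
        cls = de.classify_genes(y, labels, sf=np.ones(19), alpha=np.full(3, 0.1))
        assert (cls["category"] == "IE").all()
        np.testing.assert_allclose(cls["loglik_CX"], cls["loglik_H0"], atol=1e-6)

    def test_label_swap_symmetry_cr_tm(self, planted_triple):
        """Swapping adult and ESC labels must swap CR and TM exactly."""
        _, y, lab, sf, alpha, cls = planted_triple
        swapped = np.where(lab == "adult", "ESC", np.where(lab == "ESC", "adult", lab))
        cls_sw = de.classify_genes(y, swapped, sf, alpha, p_threshold=1e-3)
        mapping = {"CR": "TM", "TM": "CR", "AR": "AR", "IE": "IE", "PTM": "PTM", "PAR": "PAR"}
        assert (cls_sw["category"] == cls["category"].map(mapping)).all()


class TestPermutationFDR:
    def test_too_few_permutations_rejected(self, null_triple):
        y, lab, sf, alpha = null_triple
        with pytest.raises(ValueError, match="n_perm"):
            de.permutation_fdr(y, lab, sf, alpha, n_perm=10)

    def test_null_data_reports_high_fdr_and_no_threshold(self, null_triple):
        y, lab, sf, alpha = null_triple
        fdr = de.permutation_fdr(y, lab, sf, alpha, n_perm=30, seed=1)
        assert fdr.t_star is None
        assert fdr.q_values.min() > 0.05
        # zero-rejection convention: below the smallest observed min_p -> 1
        assert fdr.fdr_at(0.0) == 1.0

    def test_signal_data_yields_operating_threshold(self, planted_triple):
        _, y, lab, sf, alpha, _ = planted_triple
        fdr = de.permutation_fdr(y, lab, sf, alpha, n_perm=30, seed=2)
        assert fdr.t_star is not None
        assert fdr.fdr_at(fdr.t_star, monotone=True) <= 0.05
        # 30% of genes carry 4-fold effects: plenty of sub-threshold q-values
        assert (fdr.q_values <= 0.05).sum() > 300


class TestSignificantGenes:
    def _frame(self, q_ipsc, q_esc, category, q_value):
        return pd.DataFrame(
            {
                "gene_id": [f"g{i}" for i in range(len(q_ipsc))],
                "q_ipsc": q_ipsc,
                "q_esc": q_esc,
                "category": category,
                "q_value": q_value,
            }
        )

    def test_fold_change_filter_boundary(self):
        # 1.2-fold excluded; exactly 1.5-fold included (inclusive bound)
        df = self._frame([120.0, 150.0], [100.0, 100.0], ["TM", "TM"], [0.01, 0.01])
        out = de.significant_genes(df)
        assert list(out["genes"]["gene_id"]) == ["g1"]

    def test_direction_and_table_counts(self):
        df = self._frame(
            [300.0, 50.0, 200.0, 400.0],
            [100.0, 100.0, 100.0, 100.0],
            ["TM", "AR", "PTM", "CR"],  # CR never tabulated
            [0.01, 0.01, 0.01, 0.001],
        )
        out = de.significant_genes(df)
        table = out["table"]
        assert table.loc["TM", "activation"] == 1
        assert table.loc["AR", "silencing"] == 1
        assert table.loc["PTM", "activation"] == 1
        assert out["n_significant"] == 3

    def test_planted_tm_recovery_with_fdr(self):
        prop = {"IE": 0.99, "TM": 0.01}
        sim = sd.simulate_three_way_counts(
            5000, de_proportions=prop, effect_log2fc=2.0, seed=54
        )
        y, lab = sim["counts"].values, sim["class_labels"]
        sf = de.size_factors(y)
        alpha = de.estimate_dispersions(y, lab, sf).alpha
        fdr = de.permutation_fdr(y, lab, sf, alpha, n_perm=30, seed=3)
        thr = fdr.t_star if fdr.t_star is not None else 1e-4
        cls = de.classify_genes(y, lab, sf, alpha, p_threshold=thr)
        out = de.significant_genes(cls, q_values=fdr.q_values)
        n_tm = out["table"].loc[["TM", "PTM"]].to_numpy().sum()
        truth_tm = (sim["truth"]["category"] == "TM").sum()  # 50
        assert 0.8 * truth_tm <= n_tm <= 1.2 * truth_tm
        wrong = out["genes"]["gene_id"].isin(
            sim["truth"].loc[sim["truth"]["category"] == "IE", "gene_id"]
        ).sum()
        assert wrong <= 5


class TestHierarchicalProportions:
    def test_em_objective_monotone_and_recovery(self):
        sim = sd.simulate_three_way_counts(
            4000,
            de_proportions={"IE": 0.9, "CR": 0.04, "TM": 0.03, "AR": 0.02, "CX": 0.01},
            effect_log2fc=2.0,
            seed=55,
        )
        y, lab = sim["counts"].values, sim["class_labels"]
        sf = de.size_factors(y)
        alpha = de.estimate_dispersions(y, lab, sf).alpha
        cls = de.classify_genes(y, lab, sf, alpha)
        mix = de.hierarchical_proportions(cls, n_samples=y.shape[1])
        trace = np.array(mix.objective_trace)
        assert (np.diff(trace) >= -1e-9).all()
        truth = sim["truth"]["category"].value_counts(normalize=True)
        for cat in ("IE", "CR", "TM", "AR"):
            assert mix.pi[cat] == pytest.approx(truth[cat], abs=0.03)
        assert abs(sum(mix.pi.values()) - 1.0) < 1e-9

    def test_all_null_concentrates_on_ie(self, null_triple):
        y, lab, sf, alpha = null_triple
        cls = de.classify_genes(y, lab, sf, alpha)
        mix = de.hierarchical_proportions(cls, n_samples=y.shape[1])
        assert mix.pi["IE"] >= 0.95


def _isoform_counts(rng, n_genes, p_by_class, depth, labels):
    k = np.zeros((n_genes, len(labels)))
    n = rng.poisson(depth, size=(n_genes, len(labels))) + 1
    for c, p in p_by_class.items():
        m = labels == c
        k[:, m] = rng.binomial(n[:, m].astype(int), p)
    return k, n


class TestIsoformRatio:
    labels = np.array(["adult"] * 6 + ["iPSC"] * 9 + ["ESC"] * 4)

    def test_equal_proportions_classified_invariant(self, rng):
        k, n = _isoform_counts(
            rng, 30, {"adult": 0.6, "iPSC": 0.6, "ESC": 0.6}, 200, self.labels
        )
        out = de.isoform_ratio_test(k, n, self.labels)
        assert (out["results"]["category"] == "IE").mean() > 0.9

    def test_quantifier_disagreement_excluded(self, rng):
        k, n = _isoform_counts(rng, 4, {"adult": 0.6, "iPSC": 0.6, "ESC": 0.6}, 200, self.labels)
        gene_ids = [f"g{j}" for j in range(4)]
        agreement = pd.DataFrame(
            {
                "gene_id": gene_ids * 2,
                "quantifier": ["cufflinks"] * 4 + ["miso"] * 4,
                "iso1": ["t1", "t1", "t1", "t1"] + ["t1", "t2", "t1", "t1"],
                "iso2": ["t2"] * 8,
            }
        )
        out = de.isoform_ratio_test(k, n, self.labels, agreement=agreement, gene_ids=gene_ids)
        assert out["n_excluded_disagreement"] == 1
        assert out["n_tested"] == 3
        assert "g1" not in set(out["results"]["gene_id"])

    def test_planted_memory_on_isoform_fraction_detected(self, rng):
        # adult = iPSC = 0.8, ESC = 0.5: transcriptional memory of splicing
        k, n = _isoform_counts(
            rng, 200, {"adult": 0.8, "iPSC": 0.8, "ESC": 0.5}, 200, self.labels
        )
        out = de.isoform_ratio_test(k, n, self.labels, p_threshold=1e-3)
        assert (out["results"]["category"] == "TM").mean() >= 0.9
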