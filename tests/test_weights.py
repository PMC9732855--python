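"""Weight training: heritability estimator, model fits, CV selection."""

import numpy as np
import pytest

import xwas
from xwas.errors import XwasError
from xwas.panel import ReferencePanel
from xwas.simulate import simulate_gene_model, simulate_trait
from xwas.weights import (H2Estimate, default_ridge_penalty, estimate_cis_h2,
                          filter_heritable, fit_weight_models,
                          marginal_qtl_scan)


class TestCisH2:
    def test_null_p_values_roughly_uniform(self, big_panel):
        # cis_h2 = 0: the one-sided HE test P should be uniform; check the
        # rejection rate at 0.05 over replicates (binomial 3-sigma band)
        model = simulate_gene_model(big_panel, 75001, n_causal=2, cis_h2=0.0,
                                    seed=1)
        reps = 150
        ps = []
        for rep in range(reps):
            trait = simulate_trait(big_panel, model, seed=rep)
            ps.append(estimate_cis_h2(big_panel, trait, big_panel.snp_ids).h2_p)
        frac = np.mean(np.asarray(ps) < 0.05)
        band = 3 * np.sqrt(0.05 * 0.95 / reps)
        assert abs(frac - 0.05) < band + 0.01

    def test_full_heritability_recovered(self, big_panel):
        model = simulate_gene_model(big_panel, 75001, n_causal=3, cis_h2=1.0,
                                    seed=2)
        hi = 0
        for rep in range(40):
            trait = simulate_trait(big_panel, model, seed=rep)
            est = estimate_cis_h2(big_panel, trait, big_panel.snp_ids)
            hi += est.h2_est >= 0.9
        assert hi >= 0.95 * 40 - 2

    def test_permuted_trait_centres_on_zero(self, big_panel):
        model, trait = xwas.simulate_gene_trait(big_panel, 75001, n_causal=2,
                                                cis_h2=0.8, seed=3)
        rng = np.random.default_rng(0)
        raw = [estimate_cis_h2(big_panel, rng.permutation(trait),
                               big_panel.snp_ids).h2_raw for _ in range(50)]
        assert abs(np.mean(raw)) < 0.05

    def test_too_few_individuals_rejected(self):
        panel = xwas.simulate_reference_panel(8, 5, 0.0, (0.3, 0.5), seed=2)
        with pytest.raises(XwasError, match="10 individuals"):
            estimate_cis_h2(panel, np.zeros(8), panel.snp_ids)


class TestFitWeightModels:
    def test_top1_selects_causal_snp_without_ld(self):
        panel = xwas.simulate_reference_panel(500, 10, 0.0, (0.2, 0.5), seed=4)
        model, trait = xwas.simulate_gene_trait(panel, 25001, n_causal=1,
                                                cis_h2=0.8, seed=4)
        gw = fit_weight_models(panel, trait, panel.snp_ids, methods=("top1",),
                               seed=0)
        # oracle: argmax marginal |correlation|
        X = panel.standardized()
        y = (trait - trait.mean()) / trait.std()
        oracle = int(np.argmax(np.abs(X.T @ y)))
        assert panel.snp_ids[oracle] == model.causal_snp_ids[0]
        assert gw.snp_ids[int(np.flatnonzero(gw.W)[0])] == model.causal_snp_ids[0]

    def test_ridge_matches_closed_form(self):
        # 2-SNP toy with fixed dosages: weights must equal
        # (X'X + kappa I)^-1 X'y computed by direct inversion
        G = np.array([[0, 1], [1, 2], [2, 0], [1, 1], [0, 2], [2, 1]], float)
        snps = __import__("pandas").DataFrame({
            "snp_id": ["rs1", "rs2"], "chrom": "1", "pos": [100, 200],
            "a1": "A", "a2": "C",
            "maf": np.minimum(G.mean(0) / 2, 1 - G.mean(0) / 2)})
        panel = ReferencePanel(G, snps)
        y = np.array([0.3, 1.2, -0.5, 0.1, 0.9, -0.2])
        kappa = 2.5
        gw = fit_weight_models(panel, y, panel.snp_ids, methods=("ridge_blup",),
                               cv_folds=2, seed=0, ridge_penalty=kappa,
                               h2=H2Estimate(0.5, 0.5, 0.5, False))
        X = panel.standardized()
        ys = (y - y.mean()) / y.std()
        expected = np.linalg.inv(X.T @ X + kappa * np.eye(2)) @ (X.T @ ys)
        np.testing.assert_allclose(gw.W, expected, atol=1e-10)

    def test_pure_noise_flagged_non_predictive(self, small_panel):
        rng = np.random.default_rng(8)
        flags = []
        for rep in range(10):
            gw = fit_weight_models(small_panel, rng.standard_normal(200),
                                   small_panel.snp_ids[:10],
                                   methods=("top1", "ridge_blup"), seed=rep)
            flags.append(gw.predictive)
        assert sum(flags) <= 3

    def test_selected_model_has_best_cv_r2(self, big_panel):
        model, trait = xwas.simulate_gene_trait(big_panel, 75001, n_causal=3,
                                                cis_h2=0.6, seed=6)
        gw = fit_weight_models(big_panel, trait, big_panel.snp_ids,
                               methods=("top1", "ridge_blup", "elastic_net"),
                               seed=1)
        assert gw.cv_r2 == max(gw.cv_r2_by_method.values())

    def test_spike_slab_recovers_sparse_signal(self):
        panel = xwas.simulate_reference_panel(300, 8, 0.0, (0.2, 0.5), seed=9)
        model, trait = xwas.simulate_gene_trait(panel, 20001, n_causal=1,
                                                cis_h2=0.8, seed=9)
        gw = fit_weight_models(panel, trait, panel.snp_ids,
                               methods=("spike_slab",), cv_folds=3, seed=0)
        causal = model.causal_snp_ids[0]
        j = gw.snp_ids.index(causal)
        assert np.abs(gw.W)[j] == np.abs(gw.W).max()
        assert gw.cv_r2 > 0.4

    def test_orientation_invariance(self, small_panel):
        # flipping a1/a2 and recoding dosages flips the weight sign and
        # leaves predicted trait values unchanged
        model, trait = xwas.simulate_gene_trait(small_panel, 125001,
                                                n_causal=2, cis_h2=0.7, seed=10)
        cis = small_panel.snp_ids[:12]
        gw = fit_weight_models(small_panel, trait, cis,
                               methods=("ridge_blup",), seed=0)
        G = small_panel.genotypes.copy()
        snps = small_panel.snps.copy()
        flip_idx = [1, 4, 7]
        G[:, flip_idx] = 2 - G[:, flip_idx]
        snps.loc[flip_idx, ["a1", "a2"]] = snps.loc[flip_idx, ["a2", "a1"]].to_numpy()
        flipped_panel = ReferencePanel(G, snps)
        gw_f = fit_weight_models(flipped_panel, trait, cis,
                                 methods=("ridge_blup",), seed=0)
        sign = np.ones(12)
        sign[flip_idx] = -1
        np.testing.assert_allclose(gw_f.W, sign * gw.W, atol=1e-8)
        pred = small_panel.standardized(cis) @ gw.W
        pred_f = flipped_panel.standardized(cis) @ gw_f.W
        np.testing.assert_allclose(pred, pred_f, atol=1e-8)

    def test_cv_r2_approaches_h2_with_sample_size(self):
        means = {}
        for n in (200, 2000):
            panel = xwas.simulate_reference_panel(n, 10, 0.2, (0.2, 0.5), seed=3)
            r2 = []
            for rep in range(5):
                model, trait = xwas.simulate_gene_trait(
                    panel, 25001, n_causal=3, cis_h2=0.5, seed=100 + rep)
                gw = fit_weight_models(panel, trait, panel.snp_ids,
                                       methods=("ridge_blup",), seed=rep)
                r2.append(gw.cv_r2)
            means[n] = np.mean(r2)
        assert means[200] < means[2000] <= 0.55


class TestFilterHeritable:
    def _gene(self, p):
        return xwas.GeneWeights("g", "1", ["rs1"], [1], ["A"], ["C"], [0.3],
                                np.array([1.0]), "top1", 0.1, 0.5, 0.5, p)

    def test_alpha_one_retains_all_and_alpha_zero_none(self):
        genes = [self._gene(p) for p in (0.001, 0.5, 0.9)]
        assert len(filter_heritable(genes, 1.0)) == 3
        assert len(filter_heritable(genes, 0.0)) == 0

    def test_null_retention_is_binomial(self, big_panel):
        # with uniform null P values the retention rate at alpha = 0.05
        # should be ~5% (cheap stand-in for the 1000-gene binomial check)
        model = simulate_gene_model(big_panel, 75001, n_causal=2, cis_h2=0.0,
                                    seed=12)
        genes = []
        for rep in range(100):
            trait = simulate_trait(big_panel, model, seed=500 + rep)
            est = estimate_cis_h2(big_panel, trait, big_panel.snp_ids)
            genes.append(self._gene(est.h2_p))
        kept = len(filter_heritable(genes, 0.05))
        assert kept <= 100 * 0.05 + 3 * np.sqrt(100 * 0.05 * 0.95) + 1


class TestMarginalQtlScan:
    def test_z_matches_direct_regression(self, small_panel):
        model, trait = xwas.simulate_gene_trait(small_panel, 125001,
                                                n_causal=1, cis_h2=0.6, seed=13)
        scan = marginal_qtl_scan(small_panel, trait, small_panel.snp_ids[:5])
        y = (trait - trait.mean()) / trait.std()
        for _, row in scan.iterrows():
            x = small_panel.standardized([row["snp_id"]])[:, 0]
            r = float(np.corrcoef(x, y)[0, 1])
            t = r * np.sqrt((len(y) - 2) / (1 - r**2))
            assert row["z"] == pytest.approx(t, rel=1e-6)


def test_default_ridge_penalty_monotone_in_h2():
    assert default_ridge_penalty(10, 0.2) > default_ridge_penalty(10, 0.8)
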