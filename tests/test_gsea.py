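"""Enrichment score, permutation nulls, NES and the GSEA driver."""

import itertools

import numpy as np
import pandas as pd
import pytest

import xwas
from xwas.errors import XwasError
from xwas.gsea import (RankedGeneList, XwasScorer, enrichment_score, gsea_null,
                       nes_and_p, rank_genes, run_gsea)
from xwas.simulate import GeneSetCollection


def brute_force_es(gs, membership):
    """Independent evaluation of the running-sum formula by explicit loops."""
    n = len(gs)
    n_c = sum(membership)
    n_r = sum(abs(g) for g, m in zip(gs, membership) if m)
    best = 0.0
    running = 0.0
    for g, m in zip(gs, membership):
        if m:
            running += abs(g) / n_r
        else:
            running -= 1.0 / (n - n_c)
        best = max(best, running)
    return best


RANKED = rank_genes({"gene1": 3.0, "gene2": 2.0, "gene3": 1.0})


class TestEnrichmentScore:
    def test_top_gene_set_scores_one(self):
        assert enrichment_score(RANKED, {"gene1"}) == 1.0

    def test_bottom_gene_set_scores_zero(self):
        assert enrichment_score(RANKED, {"gene3"}) == 0.0

    def test_full_universe_scores_one(self):
        assert enrichment_score(RANKED, {"gene1", "gene2", "gene3"}) \
            == pytest.approx(1.0, abs=1e-12)

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(17)
        for _ in range(50):
            n = int(rng.integers(3, 15))
            gs = np.sort(np.abs(rng.standard_normal(n)))[::-1]
            ranked = RankedGeneList(np.array([f"g{i}" for i in range(n)]), gs)
            k = int(rng.integers(1, n))
            members = set(rng.choice([f"g{i}" for i in range(n)], k, replace=False))
            mask = [g in members for g in ranked.gene_ids]
            assert enrichment_score(ranked, members) == \
                pytest.approx(brute_force_es(gs, mask), abs=1e-12)

    def test_scale_invariance(self):
        rng = np.random.default_rng(3)
        gs = np.sort(np.abs(rng.standard_normal(20)))[::-1]
        ranked = RankedGeneList([f"g{i}" for i in range(20)], gs)
        scaled = RankedGeneList([f"g{i}" for i in range(20)], 7.3 * gs)
        members = {f"g{i}" for i in (0, 4, 9, 15)}
        assert enrichment_score(ranked, members) == \
            pytest.approx(enrichment_score(scaled, members), abs=1e-12)

    def test_es_range(self):
        rng = np.random.default_rng(5)
        for _ in range(30):
            gs = np.sort(np.abs(rng.standard_normal(12)))[::-1]
            ranked = RankedGeneList([f"g{i}" for i in range(12)], gs)
            k = int(rng.integers(1, 12))
            members = set(rng.choice([f"g{i}" for i in range(12)], k, replace=False))
            assert 0.0 <= enrichment_score(ranked, members) <= 1.0

    def test_all_zero_member_statistics_give_zero(self):
        ranked = RankedGeneList(["a", "b", "c"], [2.0, 0.0, 0.0])
        assert enrichment_score(ranked, {"b", "c"}) == 0.0

    def test_disjoint_set_rejected(self):
        with pytest.raises(XwasError):
            enrichment_score(RANKED, {"not_a_gene"})


class TestRankGenes:
    def test_orders_by_magnitude_with_lexicographic_ties(self):
        ranked = rank_genes({"b": -3.0, "a": 3.0, "c": 1.0})
        assert ranked.gene_ids.tolist() == ["a", "b", "c"]

    def test_signed_mode(self):
        ranked = rank_genes({"b": -3.0, "a": 2.0}, signed=True)
        assert ranked.gene_ids.tolist() == ["a", "b"]


class TestGseaNull:
    def test_single_draw_in_range_and_deterministic(self):
        rng = np.random.default_rng(0)
        es = gsea_null(2, 1, "gene_shuffle", rng, ranked=RANKED)
        assert 0.0 <= es[0] <= 1.0
        a = gsea_null(2, 50, "gene_shuffle", np.random.default_rng(5), ranked=RANKED)
        b = gsea_null(2, 50, "gene_shuffle", np.random.default_rng(5), ranked=RANKED)
        np.testing.assert_array_equal(a, b)
        with pytest.raises(XwasError):
            gsea_null(2, 0, "gene_shuffle", rng, ranked=RANKED)

    def test_gene_shuffle_matches_enumeration(self):
        # brute-force distribution over all C(N, k) memberships (N = 8, k = 3)
        rng = np.random.default_rng(11)
        gs = np.sort(np.abs(rng.standard_normal(8)))[::-1]
        ids = [f"g{i}" for i in range(8)]
        ranked = RankedGeneList(ids, gs)
        exact = {}
        for combo in itertools.combinations(range(8), 3):
            mask = [i in combo for i in range(8)]
            es = round(brute_force_es(gs, mask), 12)
            exact[es] = exact.get(es, 0) + 1
        total = sum(exact.values())
        exact = {k: v / total for k, v in exact.items()}
        draws = gsea_null(3, 20000, "gene_shuffle", np.random.default_rng(1),
                          ranked=ranked)
        emp = pd.Series(np.round(draws, 12)).value_counts(normalize=True)
        tv = 0.5 * sum(abs(emp.get(k, 0.0) - p) for k, p in exact.items()) \
            + 0.5 * sum(p for k, p in emp.items() if round(k, 12) not in exact)
        assert tv < 0.05

    def test_snp_shuffle_mode(self, small_panel):
        model, trait = xwas.simulate_gene_trait(small_panel, 125001, n_causal=2,
                                                cis_h2=0.6, seed=41, gene_id="g1")
        gwas = xwas.simulate_gwas_summary(small_panel, [model], seed=41)
        gw = xwas.fit_weight_models(small_panel, trait, small_panel.snp_ids[:10],
                                    methods=("ridge_blup",), seed=0, gene_id="g1")
        gw2 = xwas.fit_weight_models(small_panel, trait, small_panel.snp_ids[10:20],
                                     methods=("ridge_blup",), seed=0, gene_id="g2")
        scorer = XwasScorer.from_inputs(gwas, [gw, gw2], small_panel)
        null = gsea_null(1, 25, "snp_shuffle", np.random.default_rng(2),
                         scorer=scorer, gene_set={"g1"})
        assert null.shape == (25,)
        assert ((null >= 0) & (null <= 1)).all()


class TestNesAndP:
    def test_centering(self):
        nes, _ = nes_and_p(0.3, [0.2, 0.3, 0.4])
        assert nes == 0.0

    def test_hand_arithmetic_sample_sd(self):
        nes, _ = nes_and_p(0.6, [0.2, 0.4], 2)
        assert nes == pytest.approx((0.6 - 0.3) / np.std([0.2, 0.4], ddof=1))
        assert nes == pytest.approx(2.1213203435596424, abs=1e-12)

    def test_p_boundary_when_null_dominates(self):
        _, p = nes_and_p(0.1, [0.2, 0.4, 0.6], 3)
        assert p == 1.0

    def test_zero_sd_flags_nes_missing(self):
        nes, p = nes_and_p(0.5, [0.2, 0.2, 0.2], 3)
        assert np.isnan(nes)
        assert p == 1 / 4

    def test_null_nes_standardized(self):
        rng = np.random.default_rng(6)
        null = rng.beta(2, 5, size=2000)
        nes = np.array([nes_and_p(x, null)[0] for x in null[:200]])
        assert abs(nes.mean()) < 0.2
        assert 0.8 < nes.std() < 1.2


class TestRunGsea:
    def _stats(self, n=60, seed=0):
        rng = np.random.default_rng(seed)
        return pd.Series(np.abs(rng.standard_normal(n)),
                         index=[f"g{i:03d}" for i in range(n)])

    def test_enriched_sets_score_lower_p(self):
        stats = self._stats()
        order = stats.sort_values(ascending=False).index.tolist()
        coll = xwas.simulate_chemical_sets(order, 12, (5, 10), 4, 8.0, order,
                                           seed=3)
        out = run_gsea(coll, stats=stats, n_perm=500, seed=1)
        enr = out[out["set_id"].isin(list(coll.sets)[:4])]["p_emp"]
        bg = out[~out["set_id"].isin(list(coll.sets)[:4])]["p_emp"]
        assert enr.median() < bg.median()

    def test_duplicate_set_same_es_and_p_without_substreams(self):
        stats = self._stats()
        members = tuple(stats.index[:8])
        coll = GeneSetCollection({"s_a": ("d", members), "s_b": ("d", members)},
                                 tuple(stats.index))
        out = run_gsea(coll, stats=stats, n_perm=200, seed=5,
                       independent_substreams=False).set_index("set_id")
        assert out.loc["s_a", "es"] == out.loc["s_b", "es"]
        assert out.loc["s_a", "p_emp"] == out.loc["s_b", "p_emp"]

    def test_result_independent_of_set_ordering(self):
        stats = self._stats()
        sets = {f"s{i}": ("d", tuple(stats.index[i * 5:(i + 1) * 5]))
                for i in range(5)}
        coll_fwd = GeneSetCollection(dict(sets), tuple(stats.index))
        coll_rev = GeneSetCollection(dict(reversed(sets.items())),
                                     tuple(stats.index))
        a = run_gsea(coll_fwd, stats=stats, n_perm=200, seed=9).set_index("set_id")
        b = run_gsea(coll_rev, stats=stats, n_perm=200, seed=9).set_index("set_id")
        pd.testing.assert_frame_equal(a.sort_index(), b.sort_index())

    def test_empty_collection_rejected(self):
        with pytest.raises(XwasError):
            run_gsea(GeneSetCollection({}, ("a",)), stats=self._stats())
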