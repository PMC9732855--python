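# xwas

Summary-statistic **PWAS/TWAS association**, Bayesian **colocalization** and
chemical **gene-set enrichment**, with a synthetic-cohort simulator that makes
the whole pipeline testable end to end without any external data.

## The problem

Proteome- and transcriptome-wide association studies (PWAS/TWAS — collectively
"X-WAS") ask whether a trait is associated with the *genetically predicted*
abundance of each protein or transcript. They combine three inputs that are
usually produced by different consortia: GWAS summary Z-scores, per-gene
cis-SNP weight models trained on a molecular reference cohort (pQTL/eQTL
panels), and an LD reference panel. For a gene with weights `W`, GWAS scores
`Z` and SNP-correlation matrix `S`, the gene statistic is

```
z = W'Z / √(W'SW)          z ~ N(0, 1) under the null
```

Significance is assessed by a permutation test that shuffles the assignment
of weights to SNPs within the locus — conditioning on the GWAS signal and the
LD — with the add-one empirical P `(1 + #{|z_perm| ≥ |z_obs|})/(n_perm + 1)`.
Genes passing the screen are colocalized against the QTL signal (five-
hypothesis posterior; PP4 = both signals share one causal variant), and the
gene-level statistics feed a weighted Kolmogorov–Smirnov enrichment score
over chemical–gene sets with a permutation null and normalized enrichment
scores (NES).

The real inputs of such studies (large GWAS meta-analyses, brain proteome
weight files, curated chemical–gene databases) are restricted or bulky, so
`xwas` ships a first-class synthetic-data module: LD-structured genotype
panels, cis-heritable molecular traits, GWAS Z-scores drawn from a mediation
model `Z ~ MVN(λ·S·W̃, S)` (with `W̃'SW̃ = 1`, so λ is the expected gene-level
Z), and gene sets with controlled enrichment. See `docs/methods.md` for the
model details and what the simulator does and does not emulate.

## Worked example

One mediated gene (λ = 6) on a 400-individual, 12-SNP synthetic locus:

```python
import xwas

panel = xwas.simulate_reference_panel(400, 12, 0.3, (0.1, 0.5), seed=11)
model, trait = xwas.simulate_gene_trait(panel, 30001, cis_window_bp=60000,
                                        n_causal=3, cis_h2=0.5, seed=11,
                                        lambda_effect=6.0, gene_id="PROT0001",
                                        effect_dist="rademacher")
gwas = xwas.simulate_gwas_summary(panel, [model], seed=11)
weights = xwas.fit_weight_models(panel, trait, panel.snp_ids,
                                 methods=("top1", "ridge_blup", "elastic_net"),
                                 seed=0, gene_id="PROT0001")
table = xwas.run_xwas(gwas, [weights], panel, n_perm=1000, seed=0)
print(table[["gene_id", "n_snps_used", "z_xwas", "p_asymptotic", "p_perm",
             "significant"]].to_string(index=False))
```

prints

```
   gene_id  n_snps_used   z_xwas  p_asymptotic   p_perm  significant
PROT0001           12 5.025617  5.018158e-07 0.005994         True
```

The fitted elastic-net weights (cross-validated R² 0.49, estimated cis
heritability 0.49) recover a gene Z of 5.0 — attenuated from the simulated
λ = 6 by imperfect weight estimation — and the weight-shuffle permutation P
(0.006) confirms that the specific weight/GWAS alignment, not merely the
locus-level signal, drives the association.

The full study runs from the command line:

```bash
xwas pipeline --seed 1 --out results/run1     # discovery + replication +
                                              # transcriptome, coloc, GSEA
xwas run --gwas gwas.tsv --weights w.tsv --matrix m.tsv --snps s.tsv \
         --n-perm 5000 --seed 1 --out results/assoc
xwas gsea --stats results/assoc/xwas.tsv --gmt sets.gmt --seed 1 --out results/gsea
```

`xwas pipeline` writes per-panel association, colocalization, enrichment and
intersection tables plus a manifest; every table is stamped with the config
hash and the whole run is byte-identical under a fixed seed.

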