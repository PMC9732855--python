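"""End-to-end driver: simulate -> weights -> association -> coloc -> GSEA.

The pipeline mirrors a discovery/replication design: one synthetic GWAS, two
independent "proteome" weight panels (discovery and replication cohorts) and
one "transcriptome" panel, all trained on the same LD reference.  Genes
significant in both proteome panels are intersected, compared with the
transcriptome hits, colocalized against each panel's QTL signals and the
per-panel statistics are fed to chemical gene-set enrichment.

Every stage logs its filter decisions (the per-gene skip reasons), and every
output table is stamped with the configuration hash so any stage can be
re-run from saved intermediates and checked for exact reproduction.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .association import intersect_significant, run_xwas
from .coloc import DEFAULT_PRIORS, run_coloc
from .errors import XwasError
from .gsea import XwasScorer, run_gsea
from .io import (config_hash, write_config, write_gmt, write_gwas, write_panel,
                 write_tsv_table, write_weight_panel)
from .panel import ReferencePanel
from .simulate import (TrueGeneModel, simulate_chemical_sets,
                       simulate_gwas_summary, simulate_reference_panel,
                       simulate_trait)
from .weights import estimate_cis_h2, filter_heritable, fit_weight_models, \
    marginal_qtl_scan

logger = logging.getLogger(__name__)

PANEL_TAGS = ("proteome_discovery", "proteome_replication", "transcriptome")


@dataclass
class PipelineConfig:
    """All knobs of the synthetic study, serializable to YAML."""

    seed: int = 0
    # reference panel
    n_individuals: int = 400
    n_genes: int = 200
    snps_per_gene: int = 12
    ld_decay: float = 0.3
    maf_min: float = 0.1
    maf_max: float = 0.5
    spacing_bp: int = 5000
    # gene architecture; >= 2 causal variants keeps the weight-shuffle
    # permutation null non-degenerate (a single spike weight relanding on its
    # causal SNP reproduces the observed statistic, flooring p at ~1/m)
    n_causal: int = 3
    # equal-magnitude causal effects keep every causal SNP contributing;
    # see simulate_gene_model(effect_dist=...)
    effect_dist: str = "rademacher"
    cis_h2: float = 0.5
    n_mediated: int = 3
    lambda_mediated: float = 6.0
    # weight training
    weight_methods: tuple = ("top1", "ridge_blup", "elastic_net")
    cv_folds: int = 5
    alpha_h2: float = 0.01
    # association
    n_perm_assoc: int = 500
    alpha: float = 0.05
    # colocalization
    gate_alpha: float = 0.05
    coloc_p1: float = DEFAULT_PRIORS[0]
    coloc_p2: float = DEFAULT_PRIORS[1]
    coloc_p12: float = DEFAULT_PRIORS[2]
    gwas_n: int = 50000
    # gene sets / GSEA
    n_sets: int = 30
    set_size_min: int = 5
    set_size_max: int = 20
    n_enriched_sets: int = 3
    enrichment_strength: float = 4.0
    n_perm_gsea: int = 500
    gsea_mode: str = "snp_shuffle"
    # output
    write_panel_matrix: bool = False

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["weight_methods"] = list(self.weight_methods)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise XwasError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        if "weight_methods" in d:
            d["weight_methods"] = tuple(d["weight_methods"])
        return cls(**d)


@dataclass
class GenePanelFit:
    """One cohort's trained weights and QTL scan for the retained genes."""

    tag: str
    weights: list
    qtl: dict  # gene_id -> per-SNP marginal QTL summary


@dataclass
class PipelineResult:
    config: PipelineConfig
    panel: ReferencePanel
    gene_models: list
    gwas: object
    fits: dict
    xwas_tables: dict
    intersection: pd.DataFrame
    intersection_all: pd.DataFrame
    coloc_tables: dict
    collection: object
    gsea_tables: dict
    manifest: dict


def _gene_blocks(config: PipelineConfig):
    """Gene ids with their cis SNP index ranges (disjoint blocks along one
    chromosome, anchored at the block centre)."""
    spg = config.snps_per_gene
    for g in range(config.n_genes):
        yield f"gene{g + 1:04d}", np.arange(g * spg, (g + 1) * spg)


def run_pipeline(config: PipelineConfig, out_dir=None) -> PipelineResult:
    t0 = time.perf_counter()
    root = np.random.SeedSequence(config.seed)
    (ss_panel, ss_arch, ss_traits, ss_gwas, ss_fit,
     ss_assoc, ss_sets, ss_gsea) = root.spawn(8)

    logger.info("stage 1/6: reference panel")
    m_snps = config.n_genes * config.snps_per_gene
    panel = simulate_reference_panel(
        config.n_individuals, m_snps, config.ld_decay,
        (config.maf_min, config.maf_max), np.random.default_rng(ss_panel),
        spacing_bp=config.spacing_bp)
    snp_ids = np.array(panel.snp_ids, dtype=object)
    positions = panel.snps["pos"].to_numpy()
    chrom = panel.snps["chrom"].iloc[0]

    logger.info("stage 2/6: gene architectures (%d genes, %d mediated)",
                config.n_genes, config.n_mediated)
    rng_arch = np.random.default_rng(ss_arch)
    mediated = set(rng_arch.choice(config.n_genes, size=config.n_mediated,
                                   replace=False).tolist())
    gene_models, cis_map = [], {}
    window = config.spacing_bp * config.snps_per_gene
    for g, (gene_id, idx) in enumerate(_gene_blocks(config)):
        cis = snp_ids[idx].tolist()
        cis_map[gene_id] = cis
        anchor = int(positions[idx[len(idx) // 2]])
        causal_idx = np.sort(rng_arch.choice(len(cis), size=config.n_causal,
                                             replace=False))
        if config.effect_dist == "rademacher":
            effects = rng_arch.choice([-1.0, 1.0], size=config.n_causal)
        else:
            effects = rng_arch.standard_normal(config.n_causal)
        gene_models.append(TrueGeneModel(
            gene_id=gene_id, chrom=chrom, anchor_pos=anchor,
            cis_window_bp=window,
            causal_snp_ids=[cis[i] for i in causal_idx],
            true_weights=effects,
            cis_h2=config.cis_h2,
            lambda_effect=config.lambda_mediated if g in mediated else 0.0,
        ))

    logger.info("stage 3/6: weight training on %d cohorts", len(PANEL_TAGS))
    fit_seeds = ss_fit.generate_state(len(PANEL_TAGS) * config.n_genes) % (2**31)
    trait_streams = ss_traits.spawn(len(PANEL_TAGS))
    fits = {}
    for p_i, tag in enumerate(PANEL_TAGS):
        rng_trait = np.random.default_rng(trait_streams[p_i])
        trained, qtl = [], {}
        n_nonpredictive = 0
        for g_i, model in enumerate(gene_models):
            cis = cis_map[model.gene_id]
            trait = simulate_trait(panel, model, rng_trait)
            h2 = estimate_cis_h2(panel, trait, cis)
            gw = fit_weight_models(
                panel, trait, cis, methods=config.weight_methods,
                cv_folds=config.cv_folds,
                seed=int(fit_seeds[p_i * config.n_genes + g_i]),
                gene_id=model.gene_id, h2=h2)
            if not gw.predictive:
                n_nonpredictive += 1
                logger.info("panel %s: gene %s non-predictive (cv_r2 <= 0)",
                            tag, model.gene_id)
                continue
            trained.append(gw)
            qtl[model.gene_id] = marginal_qtl_scan(panel, trait, cis)
        retained = filter_heritable(trained, config.alpha_h2)
        logger.info("panel %s: %d trained, %d non-predictive, %d heritable",
                    tag, len(trained), n_nonpredictive, len(retained))
        fits[tag] = GenePanelFit(tag, retained,
                                 {g: qtl[g] for g in (w.gene_id for w in retained)})

    logger.info("stage 4/6: GWAS simulation and association")
    gwas = simulate_gwas_summary(panel, gene_models,
                                 np.random.default_rng(ss_gwas),
                                 n_gwas=config.gwas_n)
    assoc_seeds = ss_assoc.generate_state(len(PANEL_TAGS)) % (2**31)
    xwas_tables = {
        tag: run_xwas(gwas, fits[tag].weights, panel,
                      n_perm=config.n_perm_assoc, alpha=config.alpha,
                      seed=int(assoc_seeds[i]), panel_tag=tag)
        for i, tag in enumerate(PANEL_TAGS)
    }
    discovery, replication = PANEL_TAGS[0], PANEL_TAGS[1]
    intersection = intersect_significant(
        {t: xwas_tables[t] for t in (discovery, replication)}, config.alpha)
    intersection_all = intersect_significant(xwas_tables, config.alpha)

    logger.info("stage 5/6: colocalization of %d intersected genes",
                len(intersection))
    keep = set(intersection["gene_id"]) if len(intersection) else set()
    coloc_tables = {}
    for tag in PANEL_TAGS:
        xt = xwas_tables[tag]
        xt = xt[xt["gene_id"].isin(keep)]
        coloc_tables[tag] = run_coloc(
            xt, gwas, fits[tag].qtl, gate_alpha=config.gate_alpha,
            p1=config.coloc_p1, p2=config.coloc_p2, p12=config.coloc_p12,
            gwas_n=config.gwas_n)

    logger.info("stage 6/6: chemical gene-set enrichment (%s null)",
                config.gsea_mode)
    disc_table = xwas_tables[discovery]
    order = disc_table.assign(absz=disc_table["z_xwas"].abs()) \
        .sort_values(["absz", "gene_id"], ascending=[False, True])["gene_id"].tolist()
    rng_sets = np.random.default_rng(ss_sets)
    collection = simulate_chemical_sets(
        order, config.n_sets, (config.set_size_min, config.set_size_max),
        config.n_enriched_sets, config.enrichment_strength, order, rng_sets)
    gsea_seeds = ss_gsea.generate_state(len(PANEL_TAGS)) % (2**31)
    gsea_tables = {}
    for i, tag in enumerate(PANEL_TAGS):
        xt = xwas_tables[tag]
        if config.gsea_mode == "snp_shuffle":
            scorer = XwasScorer.from_inputs(gwas, fits[tag].weights, panel)
            sub = collection_restricted(collection, set(scorer.gene_ids))
            gsea_tables[tag] = run_gsea(sub, scorer=scorer,
                                        n_perm=config.n_perm_gsea,
                                        mode="snp_shuffle",
                                        seed=int(gsea_seeds[i]))
        else:
            stats = pd.Series(xt["z_xwas"].abs().to_numpy(),
                              index=xt["gene_id"].to_numpy())
            sub = collection_restricted(collection, set(stats.index))
            gsea_tables[tag] = run_gsea(sub, stats=stats,
                                        n_perm=config.n_perm_gsea,
                                        mode="gene_shuffle",
                                        seed=int(gsea_seeds[i]))

    manifest = {
        "config_hash": config_hash(config.as_dict()),
        "seed": config.seed,
        "xwas_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "n_genes_retained": {t: len(fits[t].weights) for t in PANEL_TAGS},
        "n_intersection": int(len(intersection)),
        "wall_clock_s": round(time.perf_counter() - t0, 3),
    }
    result = PipelineResult(config, panel, gene_models, gwas, fits,
                            xwas_tables, intersection, intersection_all,
                            coloc_tables, collection, gsea_tables, manifest)
    if out_dir is not None:
        write_results(result, out_dir)
    return result


def collection_restricted(collection, universe: set):
    """Restrict a gene-set collection to a scored universe, dropping sets with
    no scorable member (the drop is the caller's logged filter)."""
    from .simulate import GeneSetCollection
    sets = {}
    for sid, (desc, members) in collection.sets.items():
        kept = tuple(g for g in members if g in universe)
        if kept:
            sets[sid] = (desc, kept)
        else:
            logger.info("gene set %s: no scorable members, skipped", sid)
    if not sets:
        raise XwasError("no gene set has scorable members")
    return GeneSetCollection(sets, tuple(sorted(universe)))


def write_results(result: PipelineResult, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = result.manifest["config_hash"]
    stamp = f"config_hash={chash}"
    write_config(result.config.as_dict(), out / "config.yaml")
    write_gwas(result.gwas, out / "gwas.tsv", header_comment=stamp)
    write_gmt(result.collection, out / "chemical_sets.gmt")
    if result.config.write_panel_matrix:
        write_panel(result.panel, out / "panel_matrix.tsv", out / "panel_snps.tsv",
                    header_comment=stamp)
    for tag in PANEL_TAGS:
        write_weight_panel(result.fits[tag].weights, out / f"weights_{tag}.tsv",
                           header_comment=stamp)
        write_tsv_table(result.xwas_tables[tag], out / f"xwas_{tag}.tsv", stamp)
        write_tsv_table(result.coloc_tables[tag], out / f"coloc_{tag}.tsv", stamp)
        write_tsv_table(result.gsea_tables[tag], out / f"gsea_{tag}.tsv", stamp)
    write_tsv_table(result.intersection, out / "intersection_discovery_replication.tsv",
                    stamp)
    write_tsv_table(result.intersection_all, out / "intersection_all_panels.tsv",
                    stamp)
    (out / "manifest.json").write_text(json.dumps(result.manifest, indent=2,
                                                  sort_keys=True) + "\n")
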