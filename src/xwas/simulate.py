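"""Synthetic cohorts with the statistical structure the pipeline assumes.

The generators produce, with no external data:

* an LD-structured genotype reference panel (AR(1) latent Gaussian thresholded
  to 0/1/2 dosages, so one ``ld_decay`` knob controls neighbour correlation);
* cis-heritable molecular traits (protein abundance / expression) from sparse
  causal architectures, the raw material for weight training;
* GWAS summary Z-scores under a mediation model
  ``Z ~ MVN(sum_g lambda_g * S * W_g, S)`` in which each mediated gene's weight
  vector is rescaled to ``W'SW = 1`` so that ``lambda_g`` is the expected
  gene-level association Z;
* chemical-style gene sets with controlled enrichment in high-statistic genes.

Every generator is a pure function of its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .association import GwasSummary
from .errors import SimulationError, XwasError
from .panel import ReferencePanel

_MAX_RETRIES = 10


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ----------------------------------------------------------------------
# Reference panel
# ----------------------------------------------------------------------

def simulate_reference_panel(n_individuals: int, m_snps: int, ld_decay: float,
                             maf_range=(0.05, 0.5), seed=0, *, chrom: str = "1",
                             spacing_bp: int = 5000, start_bp: int = 1,
                             max_retries: int = _MAX_RETRIES) -> ReferencePanel:
    """Simulate an LD-structured dosage panel.

    Two haplotypes per individual are drawn from a latent AR(1) Gaussian with
    neighbour correlation ``ld_decay`` and thresholded at the per-SNP allele
    frequency (drawn uniformly from ``maf_range``); the dosage is the sum of
    the two haplotype indicators, so ``ld_decay = 0`` gives independent SNPs
    and larger values give stronger adjacent-SNP correlation.  Positions are
    1-based, ``spacing_bp`` apart.  Monomorphic draws are retried a bounded
    number of times before failing.
    """
    if n_individuals < 2 or m_snps < 1:
        raise SimulationError("need n_individuals >= 2 and m_snps >= 1")
    if not (0.0 <= ld_decay < 1.0):
        raise SimulationError("ld_decay must lie in [0, 1)")
    lo, hi = float(maf_range[0]), float(maf_range[1])
    if not (0.0 < lo <= hi <= 0.5):
        raise SimulationError("maf_range must be within (0, 0.5]")
    rng = _as_rng(seed)
    for _ in range(max_retries):
        maf_target = rng.uniform(lo, hi, size=m_snps)
        thresholds = sps.norm.ppf(maf_target)
        dosage = np.zeros((n_individuals, m_snps))
        for _hap in range(2):
            latent = np.empty((n_individuals, m_snps))
            latent[:, 0] = rng.standard_normal(n_individuals)
            innov = rng.standard_normal((n_individuals, m_snps))
            scale = np.sqrt(1.0 - ld_decay**2)
            for j in range(1, m_snps):
                latent[:, j] = ld_decay * latent[:, j - 1] + scale * innov[:, j]
            dosage += latent < thresholds
        if np.all(dosage.var(axis=0) > 0):
            break
    else:
        raise SimulationError(
            f"monomorphic columns persisted after {max_retries} retries"
        )
    maf = np.minimum(dosage.mean(axis=0) / 2.0, 1.0 - dosage.mean(axis=0) / 2.0)
    snps = pd.DataFrame({
        "snp_id": [f"rs{i + 1}" for i in range(m_snps)],
        "chrom": chrom,
        "pos": start_bp + spacing_bp * np.arange(m_snps),
        "a1": "A",
        "a2": "C",
        "maf": maf,
    })
    return ReferencePanel(dosage, snps)


# ----------------------------------------------------------------------
# Gene models and molecular traits
# ----------------------------------------------------------------------

@dataclass
class TrueGeneModel:
    """Ground-truth cis architecture of one molecular trait.

    ``lambda_effect`` is the mediated trait effect: the expected gene-level
    association Z once the weight vector is rescaled to ``W'SW = 1``.
    """

    gene_id: str
    chrom: str
    anchor_pos: int
    cis_window_bp: int
    causal_snp_ids: list[str]
    true_weights: np.ndarray
    cis_h2: float
    lambda_effect: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.cis_h2 <= 1.0):
            raise XwasError("cis_h2 must lie in [0, 1]")
        if len(self.causal_snp_ids) != len(self.true_weights):
            raise XwasError("causal_snp_ids and true_weights length mismatch")
        self.true_weights = np.asarray(self.true_weights, dtype=float)

    def check_within_window(self, panel: ReferencePanel) -> None:
        cis = set(panel.cis_snp_ids(self.chrom, self.anchor_pos, self.cis_window_bp))
        stray = [s for s in self.causal_snp_ids if s not in cis]
        if stray:
            raise XwasError(
                f"gene {self.gene_id!r}: causal SNPs outside cis window: {stray}"
            )


def simulate_gene_model(panel: ReferencePanel, gene_anchor_pos: int, *,
                        cis_window_bp: int = 1_000_000, n_causal: int = 1,
                        cis_h2: float = 0.5, seed=0, gene_id: str = "gene",
                        chrom=None, lambda_effect: float = 0.0,
                        effect_dist: str = "normal") -> TrueGeneModel:
    """Draw a sparse causal architecture within the gene's cis window.

    ``effect_dist`` sets the per-causal-SNP effect sizes: ``normal`` draws
    N(0,1) effects; ``rademacher`` draws equal-magnitude random-sign effects,
    which guarantees every causal SNP contributes comparably (Gaussian draws
    occasionally degenerate to an effectively single-SNP architecture).
    """
    if effect_dist not in ("normal", "rademacher"):
        raise SimulationError(f"unknown effect_dist {effect_dist!r}")
    rng = _as_rng(seed)
    chrom = panel.snps["chrom"].iloc[0] if chrom is None else chrom
    cis = panel.cis_snp_ids(chrom, gene_anchor_pos, cis_window_bp)
    if not cis:
        raise SimulationError(f"gene {gene_id!r}: no SNPs in the cis window")
    if n_causal < 1 or n_causal > len(cis):
        raise SimulationError(
            f"gene {gene_id!r}: requested {n_causal} causal SNPs, {len(cis)} available"
        )
    chosen = sorted(rng.choice(len(cis), size=n_causal, replace=False))
    if effect_dist == "rademacher":
        weights = rng.choice([-1.0, 1.0], size=n_causal)
    else:
        weights = rng.standard_normal(n_causal)
    return TrueGeneModel(
        gene_id=gene_id, chrom=chrom, anchor_pos=gene_anchor_pos,
        cis_window_bp=cis_window_bp,
        causal_snp_ids=[cis[i] for i in chosen],
        true_weights=weights, cis_h2=cis_h2, lambda_effect=lambda_effect,
    )


def simulate_trait(panel: ReferencePanel, model: TrueGeneModel, seed=0) -> np.ndarray:
    """One cohort's molecular trait: standardized genetic score scaled to
    sqrt(cis_h2) plus independent N(0,1) noise scaled to sqrt(1 - cis_h2)."""
    rng = _as_rng(seed)
    X = panel.standardized(model.causal_snp_ids)
    score = X @ model.true_weights
    sd = score.std()
    if sd > 0:
        score = (score - score.mean()) / sd
    trait = np.sqrt(model.cis_h2) * score
    noise = rng.standard_normal(panel.n_individuals)
    return trait + np.sqrt(1.0 - model.cis_h2) * noise


def simulate_gene_trait(panel: ReferencePanel, gene_anchor_pos: int,
                        cis_window_bp: int = 1_000_000, n_causal: int = 1,
                        cis_h2: float = 0.5, seed=0, **kwargs):
    """Draw a gene model and one trait realization; returns ``(model, trait)``."""
    rng = _as_rng(seed)
    model = simulate_gene_model(
        panel, gene_anchor_pos, cis_window_bp=cis_window_bp, n_causal=n_causal,
        cis_h2=cis_h2, seed=rng, **kwargs)
    return model, simulate_trait(panel, model, rng)


# ----------------------------------------------------------------------
# GWAS summary statistics under mediation
# ----------------------------------------------------------------------

def simulate_gwas_summary(panel: ReferencePanel, gene_models, seed=0, *,
                          ridge: float = 1e-6, n_gwas=None) -> GwasSummary:
    """Draw one panel-wide GWAS Z vector from MVN(sum_g lambda_g S W_g, S).

    Each gene's true weight vector is first rescaled so ``W'SW = 1``, which
    makes ``lambda_g`` the expected gene-level association Z.  ``S`` is the
    panel's empirical SNP correlation, ridge-stabilized before the Cholesky
    factorization; a panel whose stabilized S is still not positive definite
    is an explicit failure.
    """
    rng = _as_rng(seed)
    S = panel.ld().S
    mean = np.zeros(panel.n_snps)
    for model in gene_models:
        if model.lambda_effect == 0.0:
            continue
        idx = panel.snp_indices(model.causal_snp_ids)
        w = np.asarray(model.true_weights, dtype=float)
        wsw = float(w @ S[np.ix_(idx, idx)] @ w)
        if wsw <= 0:
            raise SimulationError(f"gene {model.gene_id!r}: W'SW <= 0")
        w_tilde = w / np.sqrt(wsw)
        mean += model.lambda_effect * (S[:, idx] @ w_tilde)
    try:
        L = np.linalg.cholesky(S + ridge * np.eye(panel.n_snps))
    except np.linalg.LinAlgError as exc:
        raise SimulationError(
            "SNP correlation matrix not positive definite after ridge stabilization"
        ) from exc
    Z = mean + L @ rng.standard_normal(panel.n_snps)
    table = panel.snps[["snp_id", "chrom", "pos", "a1", "a2"]].copy()
    table["z"] = Z
    if n_gwas is not None:
        table["n"] = int(n_gwas)
    return GwasSummary(table)


def flip_allele_subset(gwas: GwasSummary, fraction: float, seed=0) -> GwasSummary:
    """Re-orient a random subset of SNPs (swap a1/a2, negate Z).

    The flipped summary is statistically identical; it exists to exercise
    allele harmonization on import.
    """
    rng = _as_rng(seed)
    df = gwas.table.copy()
    flip = rng.random(len(df)) < fraction
    df.loc[flip, ["a1", "a2"]] = df.loc[flip, ["a2", "a1"]].to_numpy()
    df.loc[flip, "z"] = -df.loc[flip, "z"]
    return GwasSummary(df)


# ----------------------------------------------------------------------
# Chemical-style gene sets
# ----------------------------------------------------------------------

@dataclass
class GeneSetCollection:
    """Named gene sets over a universe of scorable genes (GMT semantics)."""

    sets: dict[str, tuple[str, tuple[str, ...]]]  # set_id -> (description, members)
    universe: tuple[str, ...]

    def __post_init__(self) -> None:
        uni = set(self.universe)
        for set_id, (_desc, members) in self.sets.items():
            if not members:
                raise XwasError(f"gene set {set_id!r} is empty")
            if len(set(members)) != len(members):
                raise XwasError(f"gene set {set_id!r} has duplicate members")
            stray = [g for g in members if g not in uni]
            if stray:
                raise XwasError(
                    f"gene set {set_id!r} has members outside the universe: {stray[:5]}"
                )

    def __len__(self) -> int:
        return len(self.sets)

    def members(self, set_id: str) -> tuple[str, ...]:
        return self.sets[set_id][1]


def simulate_chemical_sets(universe, n_sets: int, size_range, n_enriched: int,
                           enrichment_strength: float, xwas_ranks, seed=0
                           ) -> GeneSetCollection:
    """Gene sets with controlled enrichment in high-statistic genes.

    ``xwas_ranks`` is the universe ordered best-first (e.g. by |z|).  The first
    ``n_enriched`` sets sample members with probability weight
    ``exp(enrichment_strength * (1 - rank_percentile))`` so strength 0 is
    uniform and large strength concentrates membership at the top of the
    ranking; the remaining sets sample uniformly.
    """
    universe = list(universe)
    lo, hi = int(size_range[0]), int(size_range[1])
    if not (2 <= lo <= hi <= len(universe)):
        raise SimulationError(
            f"size_range {size_range} invalid for universe of {len(universe)} genes"
        )
    if n_enriched > n_sets:
        raise SimulationError("n_enriched exceeds n_sets")
    order = list(xwas_ranks)
    if set(order) != set(universe):
        raise SimulationError("xwas_ranks must be a permutation of the universe")
    rng = _as_rng(seed)
    n = len(universe)
    pct = {g: i / max(n - 1, 1) for i, g in enumerate(order)}
    w_enriched = np.array([np.exp(enrichment_strength * (1.0 - pct[g]))
                           for g in universe])
    w_enriched /= w_enriched.sum()
    sets = {}
    for k in range(n_sets):
        size = int(rng.integers(lo, hi + 1))
        p = w_enriched if k < n_enriched else None
        members = rng.choice(n, size=size, replace=False, p=p)
        tag = "enriched" if k < n_enriched else "background"
        sets[f"chem{k + 1:04d}"] = (tag, tuple(universe[i] for i in members))
    return GeneSetCollection(sets, tuple(universe))
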