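"""Bayesian colocalization of GWAS and QTL signals at a locus.

Under the single-causal-variant assumption, per-SNP Wakefield approximate
Bayes factors for each trait are combined over the five hypotheses

    H0: no association with either trait
    H1/H2: association with trait 1 / trait 2 only
    H3: both traits, different causal variants
    H4: both traits, one shared causal variant

with per-SNP priors p1, p2 (single-trait causal) and p12 (shared causal).
PP4 is the posterior that both signals are driven by the same variant.  All
sums are done in log space, so |z| up to 40 does not overflow.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .errors import XwasError

DEFAULT_PRIORS = (1e-4, 1e-4, 1e-5)  # p1, p2, p12 (coloc's canonical defaults)
PRIOR_VAR_QUANTITATIVE = 0.15**2  # molecular traits
PRIOR_VAR_BINARY = 0.2**2  # the (binary) GWAS trait


def wakefield_abf(z, v=None, prior_var: float = PRIOR_VAR_QUANTITATIVE, *,
                  n=None, maf=None) -> np.ndarray:
    """Per-SNP log approximate Bayes factor.

    log ABF = 1/2 log(1 - r) + r z^2 / 2 with r = prior_var / (prior_var + v),
    where ``v`` is the squared standard error of the per-SNP effect.  When no
    SE is available, v is derived from the allele frequency and sample size of
    a standardized trait: v = 1 / (2 f (1 - f) n).
    """
    z = np.asarray(z, dtype=float)
    if v is None:
        if n is None or maf is None:
            raise XwasError("need either v (se^2) or both n and maf")
        f = np.asarray(maf, dtype=float)
        v = 1.0 / (2.0 * f * (1.0 - f) * np.asarray(n, dtype=float))
    v = np.broadcast_to(np.asarray(v, dtype=float), z.shape).copy()
    if np.any(v <= 0):
        raise XwasError("v (squared standard error) must be positive")
    if prior_var < 0:
        raise XwasError("prior_var must be nonnegative")
    r = prior_var / (prior_var + v)
    return 0.5 * np.log1p(-r) + r * z**2 / 2.0


@dataclass
class ColocResult:
    """Posterior probabilities of the five colocalization hypotheses."""

    gene_id: str
    n_snps: int
    pp0: float
    pp1: float
    pp2: float
    pp3: float
    pp4: float
    p1: float
    p2: float
    p12: float

    def __post_init__(self) -> None:
        pps = np.array([self.pp0, self.pp1, self.pp2, self.pp3, self.pp4])
        if np.any(pps < 0) or np.any(pps > 1):
            raise XwasError("posterior probabilities must lie in [0, 1]")
        if abs(pps.sum() - 1.0) > 1e-9:
            raise XwasError("posterior probabilities do not sum to 1")

    def as_dict(self) -> dict:
        return {"pp0": self.pp0, "pp1": self.pp1, "pp2": self.pp2,
                "pp3": self.pp3, "pp4": self.pp4}

    @property
    def top_hypothesis(self) -> str:
        pps = self.as_dict()
        return max(pps, key=pps.get)


def _logdiffexp(a: float, b: float) -> float:
    """log(exp(a) - exp(b)); -inf when the difference underflows to <= 0."""
    if b >= a:
        return -np.inf
    return a + np.log1p(-np.exp(b - a))


def coloc_pp(log_abf_trait1, log_abf_trait2, p1: float = DEFAULT_PRIORS[0],
             p2: float = DEFAULT_PRIORS[1], p12: float = DEFAULT_PRIORS[2], *,
             gene_id: str = "gene") -> ColocResult:
    """Five-hypothesis posterior from two traits' per-SNP log Bayes factors.

    H1 sums single-SNP configurations of trait 1, H2 of trait 2, H4 the shared
    configurations, and H3 the cross-product minus the shared diagonal — which
    cancels exactly for a single-SNP region, forcing pp3 = 0 there.
    """
    l1 = np.asarray(log_abf_trait1, dtype=float)
    l2 = np.asarray(log_abf_trait2, dtype=float)
    if l1.shape != l2.shape or l1.ndim != 1 or len(l1) == 0:
        raise XwasError("log ABF vectors must be equal-length 1-D arrays")
    lsum1 = float(logsumexp(l1))
    lsum2 = float(logsumexp(l2))
    lsum12 = float(logsumexp(l1 + l2))
    lh = np.array([
        0.0,
        np.log(p1) + lsum1,
        np.log(p2) + lsum2,
        np.log(p1) + np.log(p2) + _logdiffexp(lsum1 + lsum2, lsum12),
        np.log(p12) + lsum12,
    ])
    pps = np.exp(lh - logsumexp(lh))
    pps /= pps.sum()
    return ColocResult(gene_id, len(l1), *pps, p1=p1, p2=p2, p12=p12)


def run_coloc(xwas_table: pd.DataFrame, gwas, qtl_tables: dict, *,
              gate_alpha: float = 0.05, gate_on: str = "p_perm",
              p1: float = DEFAULT_PRIORS[0], p2: float = DEFAULT_PRIORS[1],
              p12: float = DEFAULT_PRIORS[2],
              prior_var_gwas: float = PRIOR_VAR_BINARY,
              prior_var_qtl: float = PRIOR_VAR_QUANTITATIVE,
              gwas_n=None) -> pd.DataFrame:
    """Colocalize each gene passing the association screen.

    Only genes with X-WAS ``gate_on`` P below ``gate_alpha`` are analyzed;
    the rest are emitted with empty posteriors and ``gated = False``.
    ``qtl_tables`` maps gene_id to its per-SNP QTL summary (GWAS dialect plus
    ``se`` and ``n``), as produced by :func:`xwas.weights.marginal_qtl_scan`.
    GWAS effect variances come from SE when a per-SNP ``se`` column exists,
    otherwise from allele frequency and sample size.
    """
    rows = []
    gdf = gwas.table.set_index("snp_id")
    for _, xrow in xwas_table.iterrows():
        gene = xrow["gene_id"]
        base = {"gene_id": gene, "n_snps": 0, "pp0": np.nan, "pp1": np.nan,
                "pp2": np.nan, "pp3": np.nan, "pp4": np.nan, "gated": False}
        if not (xrow[gate_on] < gate_alpha) or gene not in qtl_tables:
            rows.append(base)
            continue
        qtl = qtl_tables[gene]
        shared = [s for s in qtl["snp_id"] if s in gdf.index]
        if not shared:
            rows.append(base)
            continue
        q = qtl.set_index("snp_id").loc[shared]
        g = gdf.loc[shared]
        # ABFs depend on z^2 only, so allele orientation drops out
        if "se" in g.columns:
            l_gwas = wakefield_abf(g["z"], g["se"].to_numpy() ** 2, prior_var_gwas)
        else:
            n_col = g["n"] if "n" in g.columns else gwas_n
            if n_col is None:
                raise XwasError("GWAS summary has no se column and no sample size")
            maf = q["maf"] if "maf" in q.columns else None
            if maf is None:
                # fall back to QTL-panel frequencies via beta/se relationship
                raise XwasError("need per-SNP maf to derive GWAS effect variance")
            l_gwas = wakefield_abf(g["z"], None, prior_var_gwas,
                                   n=n_col, maf=maf.to_numpy())
        l_qtl = wakefield_abf(q["z"], q["se"].to_numpy() ** 2, prior_var_qtl)
        res = coloc_pp(np.asarray(l_gwas), np.asarray(l_qtl), p1, p2, p12,
                       gene_id=gene)
        base.update(res.as_dict())
        base["n_snps"] = res.n_snps
        base["gated"] = True
        rows.append(base)
    return pd.DataFrame(rows)
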