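"""Gene-level association from GWAS summary statistics (the PWAS/TWAS stage).

Given per-SNP GWAS Z-scores, a per-gene cis-SNP weight vector ``W`` and the
SNP-correlation matrix ``S`` from an LD reference panel, the gene statistic is

    z = W'Z / sqrt(W'SW)

which is standard normal when predicted abundance is unrelated to the trait.
Empirical significance is attached by permuting the assignment of weights to
SNPs within the locus (conditioning on the GWAS signal and the LD), yielding
an add-one permutation P value (1 + exceedances) / (n_perm + 1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import DegenerateWeightError, HarmonizationError, XwasError
from .panel import VALID_ALLELES, LdMatrix, ReferencePanel

logger = logging.getLogger(__name__)

_AMBIGUOUS_PAIRS = {frozenset(("A", "T")), frozenset(("C", "G"))}

GWAS_COLUMNS = ["snp_id", "chrom", "pos", "a1", "a2", "z"]


@dataclass
class GwasSummary:
    """Per-SNP GWAS association Z-scores with allele orientation.

    ``z`` is the score of the effect allele ``a1``.  An optional ``n`` column
    (per-SNP sample size) is carried through when present.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.table.reset_index(drop=True)
        missing = [c for c in GWAS_COLUMNS if c not in df.columns]
        if missing:
            raise XwasError(f"GWAS summary missing columns: {missing}")
        if df["snp_id"].duplicated().any():
            raise XwasError("duplicate snp_ids in GWAS summary")
        z = df["z"].to_numpy(dtype=float)
        if not np.all(np.isfinite(z)):
            raise XwasError("non-finite Z-scores in GWAS summary")
        bad = ~df["a1"].isin(VALID_ALLELES) | ~df["a2"].isin(VALID_ALLELES)
        if bad.any():
            raise XwasError("allele codes outside {A,C,G,T} in GWAS summary")
        self.table = df
        self._index = {s: i for i, s in enumerate(df["snp_id"])}

    @property
    def snp_ids(self) -> list[str]:
        return self.table["snp_id"].tolist()

    def row(self, snp_id: str) -> pd.Series:
        return self.table.iloc[self._index[snp_id]]

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in self._index


@dataclass
class HarmonizedGene:
    """Aligned (W, Z, S) triple for one gene, with harmonization bookkeeping."""

    gene_id: str
    snp_ids: list[str]
    W: np.ndarray
    Z: np.ndarray
    S: LdMatrix
    n_flipped: int = 0
    n_dropped_missing: int = 0
    n_dropped_ambiguous: int = 0
    n_dropped_mismatch: int = 0

    @property
    def n_snps_used(self) -> int:
        return len(self.snp_ids)


def harmonize(weights, gwas: GwasSummary, panel: ReferencePanel,
              drop_ambiguous: bool = True) -> HarmonizedGene:
    """Align a gene's weight model with the GWAS and the LD panel.

    SNPs are matched by id across the three sources.  Where the weight model's
    effect allele equals the GWAS other allele (and vice versa) the GWAS Z sign
    is flipped; strand-ambiguous pairs (A/T, C/G) are dropped when
    ``drop_ambiguous`` is set; SNPs missing from any source or with
    irreconcilable allele codes are dropped and counted.
    """
    kept, w_kept, z_kept, signs = [], [], [], []
    n_missing = n_ambig = n_mismatch = n_flip = 0
    for snp_id, w, a1, a2 in zip(weights.snp_ids, weights.W, weights.a1, weights.a2):
        if snp_id not in gwas or snp_id not in panel._index:
            n_missing += 1
            continue
        if drop_ambiguous and frozenset((a1, a2)) in _AMBIGUOUS_PAIRS:
            n_ambig += 1
            continue
        g = gwas.row(snp_id)
        if (g["a1"], g["a2"]) == (a1, a2):
            z = float(g["z"])
        elif (g["a1"], g["a2"]) == (a2, a1):
            z = -float(g["z"])
            n_flip += 1
        else:
            n_mismatch += 1
            continue
        prow = panel.snps.iloc[panel._index[snp_id]]
        if (prow["a1"], prow["a2"]) == (a1, a2):
            sign = 1.0
        elif (prow["a1"], prow["a2"]) == (a2, a1):
            sign = -1.0
        else:
            n_mismatch += 1
            continue
        kept.append(snp_id)
        w_kept.append(float(w))
        z_kept.append(z)
        signs.append(sign)
    if not kept:
        raise HarmonizationError(
            f"gene {weights.gene_id!r}: zero SNP overlap between weights, GWAS and panel"
        )
    S = panel.ld(kept)
    # orient S to the weight model's allele coding
    d = np.asarray(signs)
    S_oriented = LdMatrix(kept, d[:, None] * S.S * d[None, :])
    return HarmonizedGene(
        gene_id=weights.gene_id,
        snp_ids=kept,
        W=np.asarray(w_kept),
        Z=np.asarray(z_kept),
        S=S_oriented,
        n_flipped=n_flip,
        n_dropped_missing=n_missing,
        n_dropped_ambiguous=n_ambig,
        n_dropped_mismatch=n_mismatch,
    )


def xwas_z(W: np.ndarray, Z: np.ndarray, S, *, ridge: float = 1e-6,
           eps: float = 1e-8) -> float:
    """The gene association statistic W'Z / sqrt(W'SW).

    ``S`` may be an :class:`LdMatrix` or a plain array; a ridge ``ridge * I``
    stabilizes the quadratic form before use.
    """
    W = np.asarray(W, dtype=float)
    Z = np.asarray(Z, dtype=float)
    Smat = S.S if isinstance(S, LdMatrix) else np.asarray(S, dtype=float)
    Smat = Smat + ridge * np.eye(len(W))
    wsw = float(W @ Smat @ W)
    if wsw <= eps:
        raise DegenerateWeightError("degenerate weight variance: W'SW <= eps")
    return float(W @ Z) / np.sqrt(wsw)


def asymptotic_p(z: float) -> float:
    """Two-sided normal P value 2*Phi(-|z|)."""
    return float(2.0 * sps.norm.sf(abs(z)))


@dataclass
class PermutationResult:
    p_perm: float
    n_perm: int
    used_asymptotic: bool = False


def permutation_test(W, Z, S, n_perm: int, seed, *, mode: str = "weight_shuffle",
                     ridge: float = 1e-6) -> PermutationResult:
    """Permutation-based empirical P value for the gene statistic.

    The null reassigns weights to SNPs within the locus (``weight_shuffle``,
    preserving the GWAS signal and the LD), or flips weight signs
    (``sign_flip``, a sensitivity mode).  P = (1 + #{|z_perm| >= |z_obs|}) /
    (n_perm + 1), never smaller than 1/(n_perm + 1).
    """
    if n_perm < 1:
        raise XwasError("n_perm must be >= 1")
    if mode not in ("weight_shuffle", "sign_flip"):
        raise XwasError(f"unknown permutation mode {mode!r}")
    W = np.asarray(W, dtype=float)
    Z = np.asarray(Z, dtype=float)
    m = len(W)
    z_obs = xwas_z(W, Z, S, ridge=ridge)
    if m < 2:
        # permutation of a single weight is vacuous; fall back with a flag
        return PermutationResult(asymptotic_p(z_obs), n_perm, used_asymptotic=True)
    Smat = (S.S if isinstance(S, LdMatrix) else np.asarray(S, dtype=float))
    Smat = Smat + ridge * np.eye(m)
    rng = np.random.default_rng(seed)
    if mode == "weight_shuffle":
        Wp = rng.permuted(np.tile(W, (n_perm, 1)), axis=1)
    else:
        Wp = W[None, :] * rng.choice([-1.0, 1.0], size=(n_perm, m))
    num = Wp @ Z
    den = np.sqrt(np.einsum("ij,jk,ik->i", Wp, Smat, Wp))
    z_perm = num / den
    b = int(np.sum(np.abs(z_perm) >= abs(z_obs)))
    return PermutationResult((1 + b) / (n_perm + 1), n_perm)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted P values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def run_xwas(gwas: GwasSummary, weight_panel, panel: ReferencePanel, *,
             n_perm: int = 5000, alpha: float = 0.05, seed: int = 0,
             panel_tag: str = "panel", perm_mode: str = "weight_shuffle",
             ridge: float = 1e-6) -> pd.DataFrame:
    """Run the association stage over a weight panel.

    Returns one row per retained gene with the asymptotic, BH-adjusted and
    permutation P values; skipped genes (zero overlap, degenerate variance) are
    logged and recorded in ``df.attrs['skipped']``.
    """
    if not weight_panel:
        raise XwasError("empty weight panel")
    rows, skipped = [], {}
    ss = np.random.SeedSequence(seed)
    gene_seeds = ss.generate_state(len(weight_panel)) % (2**31)
    for gw, gseed in zip(weight_panel, gene_seeds):
        try:
            h = harmonize(gw, gwas, panel)
            z = xwas_z(h.W, h.Z, h.S, ridge=ridge)
        except (HarmonizationError, DegenerateWeightError) as exc:
            logger.info("skipping gene %s: %s", gw.gene_id, exc)
            skipped[gw.gene_id] = str(exc)
            continue
        perm = permutation_test(h.W, h.Z, h.S, n_perm, int(gseed),
                                mode=perm_mode, ridge=ridge)
        rows.append({
            "gene_id": gw.gene_id,
            "chrom": gw.chrom,
            "n_snps_used": h.n_snps_used,
            "n_snps_dropped": h.n_dropped_missing + h.n_dropped_ambiguous
                              + h.n_dropped_mismatch,
            "z_xwas": z,
            "p_asymptotic": asymptotic_p(z),
            "p_perm": perm.p_perm,
            "perm_asymptotic_fallback": perm.used_asymptotic,
            "n_perm": perm.n_perm,
            "panel_tag": panel_tag,
        })
    df = pd.DataFrame(rows)
    if len(df):
        df["p_bh"] = bh_fdr(df["p_asymptotic"].to_numpy())
        df["significant"] = df["p_perm"] < alpha
    df.attrs["skipped"] = skipped
    return df


def intersect_significant(tables: dict[str, pd.DataFrame],
                          alpha: float = 0.05) -> pd.DataFrame:
    """Genes significant (p_perm < alpha) in every supplied X-WAS table.

    Mirrors a discovery/replication design: the intersection report lists each
    shared gene with its per-panel statistic and permutation P.
    """
    common = None
    for df in tables.values():
        hits = set(df.loc[df["p_perm"] < alpha, "gene_id"])
        common = hits if common is None else common & hits
    common = sorted(common or ())
    rows = []
    for gene in common:
        row = {"gene_id": gene}
        for tag, df in tables.items():
            sub = df[df["gene_id"] == gene].iloc[0]
            row[f"z_{tag}"] = sub["z_xwas"]
            row[f"p_perm_{tag}"] = sub["p_perm"]
        rows.append(row)
    return pd.DataFrame(rows)
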