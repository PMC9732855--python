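"""Genotype reference panels and SNP-correlation (LD) matrices.

A :class:`ReferencePanel` holds a dosage matrix (individuals x SNPs, allele
counts 0/1/2 of the effect allele ``a1``) together with per-SNP metadata.  It
is the source of the SNP-correlation matrix ``S`` used throughout the
association and colocalization stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import XwasError

SNP_COLUMNS = ["snp_id", "chrom", "pos", "a1", "a2", "maf"]

VALID_ALLELES = frozenset("ACGT")


@dataclass
class LdMatrix:
    """Symmetric SNP-SNP Pearson correlation matrix with unit diagonal."""

    snp_ids: list[str]
    S: np.ndarray

    def __post_init__(self) -> None:
        S = np.asarray(self.S, dtype=float)
        m = len(self.snp_ids)
        if S.shape != (m, m):
            raise XwasError(f"LD matrix shape {S.shape} does not match {m} SNP ids")
        if not np.allclose(S, S.T, atol=1e-12, rtol=0.0):
            raise XwasError("LD matrix is not symmetric to 1e-12")
        if not np.allclose(np.diag(S), 1.0, atol=1e-8):
            raise XwasError("LD matrix diagonal is not 1")
        if m <= 2000:  # eigenvalue audit is O(m^3); skip for very large panels
            if np.linalg.eigvalsh(S).min() < -1e-8:
                raise XwasError("LD matrix has eigenvalues below -1e-8")
        self.S = S

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def stabilized(self, ridge: float = 1e-6) -> np.ndarray:
        """Return ``S + ridge * I`` (finite-panel correlation matrices are near-singular)."""
        return self.S + ridge * np.eye(self.n_snps)

    def subset(self, snp_ids: list[str]) -> "LdMatrix":
        index = {s: i for i, s in enumerate(self.snp_ids)}
        idx = np.array([index[s] for s in snp_ids], dtype=int)
        return LdMatrix(list(snp_ids), self.S[np.ix_(idx, idx)])


@dataclass
class ReferencePanel:
    """Dosage matrix plus SNP metadata.

    Parameters
    ----------
    genotypes
        ``(n_individuals, m_snps)`` array of effect-allele counts in {0, 1, 2}.
    snps
        DataFrame with columns ``snp_id, chrom, pos, a1, a2, maf``; one row per
        genotype column, in column order.  Positions are 1-based and strictly
        increasing within a chromosome.
    """

    genotypes: np.ndarray
    snps: pd.DataFrame
    _index: dict = field(init=False, repr=False)

    def __post_init__(self) -> None:
        G = np.asarray(self.genotypes, dtype=float)
        if G.ndim != 2:
            raise XwasError("genotypes must be a 2-D matrix")
        snps = self.snps.reset_index(drop=True)
        missing = [c for c in SNP_COLUMNS if c not in snps.columns]
        if missing:
            raise XwasError(f"SNP metadata missing columns: {missing}")
        if len(snps) != G.shape[1]:
            raise XwasError("SNP metadata rows do not match genotype columns")
        if snps["snp_id"].duplicated().any():
            dupes = snps.loc[snps["snp_id"].duplicated(), "snp_id"].tolist()
            raise XwasError(f"duplicate snp_ids: {dupes[:5]}")
        for _, grp in snps.groupby("chrom", sort=False):
            pos = grp["pos"].to_numpy()
            if not np.all(np.diff(pos) > 0):
                raise XwasError("positions not strictly increasing within a chromosome")
        bad = ~snps["a1"].isin(VALID_ALLELES) | ~snps["a2"].isin(VALID_ALLELES)
        if bad.any():
            raise XwasError("allele codes outside {A,C,G,T}")
        if np.any(G.var(axis=0) <= 0):
            mono = snps.loc[G.var(axis=0) <= 0, "snp_id"].tolist()
            raise XwasError(f"monomorphic SNP columns rejected: {mono[:5]}")
        maf = self._maf_from(G)
        stored = snps["maf"].to_numpy(dtype=float)
        if np.max(np.abs(maf - stored)) > 1e-12:
            raise XwasError("stored maf does not match maf recomputed from genotypes")
        if np.any(stored <= 0) or np.any(stored > 0.5):
            raise XwasError("maf must lie in (0, 0.5]")
        self.genotypes = G
        self.snps = snps
        self._index = {s: i for i, s in enumerate(snps["snp_id"])}

    @staticmethod
    def _maf_from(G: np.ndarray) -> np.ndarray:
        freq = G.mean(axis=0) / 2.0
        return np.minimum(freq, 1.0 - freq)

    # ------------------------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]

    @property
    def snp_ids(self) -> list[str]:
        return self.snps["snp_id"].tolist()

    def snp_indices(self, snp_ids) -> np.ndarray:
        try:
            return np.array([self._index[s] for s in snp_ids], dtype=int)
        except KeyError as exc:  # pragma: no cover - defensive
            raise XwasError(f"SNP {exc.args[0]!r} not in panel") from None

    def standardized(self, snp_ids=None) -> np.ndarray:
        """Dosages centred to mean 0 and scaled to variance 1 (population ddof=0)."""
        G = self.genotypes
        if snp_ids is not None:
            G = G[:, self.snp_indices(snp_ids)]
        mu = G.mean(axis=0)
        sd = G.std(axis=0)
        return (G - mu) / sd

    def ld(self, snp_ids=None) -> LdMatrix:
        """Empirical SNP-correlation matrix S for the given SNPs (default: all)."""
        ids = self.snp_ids if snp_ids is None else list(snp_ids)
        X = self.standardized(ids)
        S = X.T @ X / X.shape[0]
        S = (S + S.T) / 2.0
        np.fill_diagonal(S, 1.0)
        return LdMatrix(ids, S)

    def cis_snp_ids(self, chrom, anchor_pos: int, window_bp: int) -> list[str]:
        """SNP ids within ``anchor_pos +/- window_bp`` (1-based, inclusive) on ``chrom``."""
        snps = self.snps
        mask = (
            (snps["chrom"] == chrom)
            & (snps["pos"] >= anchor_pos - window_bp)
            & (snps["pos"] <= anchor_pos + window_bp)
        )
        return snps.loc[mask, "snp_id"].tolist()

    def subset(self, snp_ids) -> "ReferencePanel":
        idx = self.snp_indices(snp_ids)
        return ReferencePanel(self.genotypes[:, idx], self.snps.iloc[idx])
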