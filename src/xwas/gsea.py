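"""Weighted Kolmogorov-Smirnov gene-set enrichment on gene-level statistics.

Genes are ranked by their association statistic GS (largest first) and, for a
set C of N_C genes out of N, the enrichment score is the maximum of the
running sum

    ES = max_j [ sum_{hits i<=j} |GS_i|^H / N_R  -  sum_{misses i<=j} 1/(N - N_C) ]

with N_R = sum_{hits} |GS_i|^H and weight exponent H (H = 1, the original
weighted statistic).  The running sum ends at 0, so ES lies in [0, 1].  Two
permutation nulls are provided: shuffling the SNP-to-Z assignment of the GWAS
and recomputing every gene's statistic (faithful, expensive) or shuffling the
gene-to-statistic assignment (fast, equivalent to random membership).  NES
standardizes the observed ES by the null mean and SD, and the empirical P is
the add-one exceedance fraction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .association import harmonize
from .errors import XwasError

NULL_MODES = ("snp_shuffle", "gene_shuffle")


@dataclass
class RankedGeneList:
    """Genes ordered by the ranking statistic, largest first."""

    gene_ids: np.ndarray
    gs: np.ndarray
    signed: bool = False

    def __post_init__(self) -> None:
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.gs = np.asarray(self.gs, dtype=float)
        if len(self.gene_ids) != len(self.gs):
            raise XwasError("gene_ids and gs length mismatch")
        key = self.gs if self.signed else np.abs(self.gs)
        if np.any(np.diff(key) > 1e-12):
            raise XwasError("ranking statistic must be non-increasing")

    def __len__(self) -> int:
        return len(self.gene_ids)


def rank_genes(stats, *, signed: bool = False) -> RankedGeneList:
    """Rank genes by |statistic| (default) or signed statistic, descending.

    ``stats`` maps gene_id to its association statistic (dict or Series).
    Ties break deterministically by gene_id, lexicographic.
    """
    s = pd.Series(stats, dtype=float)
    key = s if signed else s.abs()
    order = sorted(s.index, key=lambda g: (-key[g], g))
    return RankedGeneList(np.array(order, dtype=object),
                          s.loc[order].to_numpy(), signed=signed)


def enrichment_score(ranked: RankedGeneList, gene_set, H: float = 1.0) -> float:
    """Exact running-sum enrichment score of ``gene_set`` on the ranking.

    Members outside the ranked universe are dropped.  N_R = 0 (all member
    statistics zero) yields ES = 0.
    """
    members = set(gene_set) & set(ranked.gene_ids.tolist())
    if not members:
        raise XwasError("gene set has no members in the ranked universe")
    hit = np.fromiter((g in members for g in ranked.gene_ids), dtype=bool,
                      count=len(ranked))
    return _es_from_mask(np.abs(ranked.gs) ** H, hit)


def _es_from_mask(weighted: np.ndarray, hit: np.ndarray) -> float:
    n = len(weighted)
    n_c = int(hit.sum())
    n_r = float(weighted[hit].sum())
    if n_r == 0.0:
        return 0.0
    inc = np.where(hit, weighted / n_r,
                   -1.0 / (n - n_c) if n_c < n else 0.0)
    running = np.cumsum(inc)
    return float(max(running.max(), 0.0))


def _es_many_memberships(weighted: np.ndarray, hits_idx: np.ndarray) -> np.ndarray:
    """ES for many memberships given as an (n_perm, k) array of sorted rank
    positions.  Evaluates the running sum only at hit positions, where the
    maximum of the running sum is attained."""
    n = len(weighted)
    n_perm, k = hits_idx.shape
    w = weighted[hits_idx]
    n_r = w.sum(axis=1, keepdims=True)
    cum_hit = np.cumsum(w, axis=1)
    ranks = np.arange(1, k + 1)
    if k < n:
        miss_before = hits_idx + 1 - ranks  # misses strictly before each hit
        vals = np.where(n_r > 0, cum_hit / np.where(n_r > 0, n_r, 1.0), 0.0) \
            - miss_before / (n - k)
    else:
        vals = np.where(n_r > 0, cum_hit / np.where(n_r > 0, n_r, 1.0), 0.0)
    es = np.maximum(vals.max(axis=1), 0.0)
    return np.where(n_r[:, 0] > 0, es, 0.0)


@dataclass
class XwasScorer:
    """Precomputed per-gene (index, weights, denominator) triples so that the
    whole gene-statistic vector can be recomputed cheaply for any permuted
    GWAS Z vector — the machinery behind the SNP-shuffle null."""

    snp_ids: list[str]
    z: np.ndarray
    gene_ids: list[str]
    _idx: list[np.ndarray]
    _w: list[np.ndarray]
    _den: np.ndarray

    @classmethod
    def from_inputs(cls, gwas, weight_panel, panel, *, ridge: float = 1e-6):
        snp_order = {s: i for i, s in enumerate(gwas.snp_ids)}
        z = gwas.table["z"].to_numpy(dtype=float).copy()
        gene_ids, idxs, ws, dens = [], [], [], []
        for gw in weight_panel:
            h = harmonize(gw, gwas, panel)
            Smat = h.S.S + ridge * np.eye(h.n_snps_used)
            den = float(np.sqrt(h.W @ Smat @ h.W))
            if den <= 0:
                continue
            # fold harmonization sign flips into the stored weights so the
            # scorer can index the raw GWAS z vector directly
            raw_z = np.array([float(gwas.row(s)["z"]) for s in h.snp_ids])
            flip = np.where(raw_z == h.Z, 1.0, -1.0)
            gene_ids.append(gw.gene_id)
            idxs.append(np.array([snp_order[s] for s in h.snp_ids]))
            ws.append(h.W * flip)
            dens.append(den)
        return cls(list(gwas.snp_ids), z, gene_ids, idxs, ws, np.asarray(dens))

    def scores(self, z_vector=None) -> np.ndarray:
        z = self.z if z_vector is None else np.asarray(z_vector, dtype=float)
        return np.array([w @ z[idx] for w, idx in zip(self._w, self._idx)]) / self._den

    def stats(self, z_vector=None, *, signed: bool = False) -> pd.Series:
        s = self.scores(z_vector)
        return pd.Series(s if signed else np.abs(s), index=self.gene_ids)


def gsea_null(gene_set_size: int, n_perm: int, mode: str, rng, *,
              ranked: RankedGeneList | None = None,
              scorer: XwasScorer | None = None, gene_set=None,
              H: float = 1.0, signed: bool = False) -> np.ndarray:
    """Sample the null ES distribution for a set of the given size.

    ``gene_shuffle`` permutes the gene-to-statistic assignment (uniform random
    membership of the same size); ``snp_shuffle`` permutes the SNP-to-Z
    assignment of the GWAS, recomputes every gene's statistic, re-ranks and
    recomputes ES for the actual member genes.
    """
    if n_perm < 1:
        raise XwasError("n_perm must be >= 1")
    if mode not in NULL_MODES:
        raise XwasError(f"unknown null mode {mode!r}")
    if mode == "gene_shuffle":
        if ranked is None:
            raise XwasError("gene_shuffle needs the ranked list")
        n = len(ranked)
        k = gene_set_size
        if not (1 <= k <= n):
            raise XwasError("set size outside [1, N]")
        weighted = np.abs(ranked.gs) ** H
        u = rng.random((n_perm, n))
        hits = np.sort(np.argpartition(u, k - 1, axis=1)[:, :k], axis=1)
        return _es_many_memberships(weighted, hits)
    if scorer is None or gene_set is None:
        raise XwasError("snp_shuffle needs the X-WAS scorer and the gene set")
    out = np.empty(n_perm)
    members = set(gene_set)
    for t in range(n_perm):
        zp = scorer.z[rng.permutation(len(scorer.z))]
        stats = scorer.stats(zp, signed=signed)
        ranked_p = rank_genes(stats, signed=signed)
        out[t] = enrichment_score(ranked_p, members, H)
    return out


def nes_and_p(es_obs: float, null_es, n_perm: int | None = None):
    """Normalized enrichment score and add-one empirical P.

    NES = (ES - mean(null)) / sd(null) with the sample SD (n-1 denominator);
    a zero null SD leaves NES undefined (NaN) while P is still computed from
    exceedance counts.
    """
    null_es = np.asarray(null_es, dtype=float)
    if len(null_es) < 2:
        raise XwasError("need at least 2 null draws")
    if n_perm is None:
        n_perm = len(null_es)
    sd = float(null_es.std(ddof=1))
    degenerate = sd <= 1e-12 * max(1.0, abs(float(null_es.mean())))
    nes = np.nan if degenerate else (es_obs - float(null_es.mean())) / sd
    b = int(np.sum(null_es >= es_obs))
    return nes, (1 + b) / (n_perm + 1)


def run_gsea(collection, *, stats=None, scorer: XwasScorer | None = None,
             n_perm: int = 20000, mode: str = "gene_shuffle", seed: int = 0,
             H: float = 1.0, signed: bool = False, alpha: float = 0.05,
             independent_substreams: bool = True) -> pd.DataFrame:
    """Enrichment of every set in the collection; one row per set.

    ``gene_shuffle`` mode needs per-gene statistics (``stats``); ``snp_shuffle``
    needs the :class:`XwasScorer` built from the GWAS, weight panel and LD
    panel (observed statistics are computed from it).  Per-set RNG substreams
    are derived from the master seed by the set's rank in sorted id order, so
    results do not depend on collection ordering; disabling substreams makes
    every set reuse the master stream (duplicated sets then give identical P).
    """
    if mode not in NULL_MODES:
        raise XwasError(f"unknown null mode {mode!r}")
    if not collection.sets:
        raise XwasError("empty gene-set collection")
    if mode == "snp_shuffle" or stats is None:
        if scorer is None:
            raise XwasError("need stats (gene_shuffle) or scorer (snp_shuffle)")
        stats = scorer.stats(signed=signed)
    ranked = rank_genes(stats, signed=signed)
    universe = set(ranked.gene_ids.tolist())
    sorted_ids = sorted(collection.sets)
    rank_of = {sid: i for i, sid in enumerate(sorted_ids)}

    null_cache = None
    if mode == "snp_shuffle":
        # one shared SNP-shuffle stream: each permutation yields a full
        # re-ranked statistic vector scored against every set at once
        rng = np.random.default_rng(np.random.SeedSequence(seed))
        masks = {}
        for sid in sorted_ids:
            members = set(collection.members(sid)) & universe
            masks[sid] = members
        null_cache = {sid: np.empty(n_perm) for sid in sorted_ids}
        for t in range(n_perm):
            zp = scorer.z[rng.permutation(len(scorer.z))]
            ranked_p = rank_genes(scorer.stats(zp, signed=signed), signed=signed)
            weighted = np.abs(ranked_p.gs) ** H
            for sid, members in masks.items():
                if not members:
                    continue
                hit = np.fromiter((g in members for g in ranked_p.gene_ids),
                                  dtype=bool, count=len(ranked_p))
                null_cache[sid][t] = _es_from_mask(weighted, hit)

    rows = []
    for sid in collection.sets:
        members = set(collection.members(sid)) & universe
        if not members:
            rows.append({"set_id": sid, "n_members_scored": 0, "es": np.nan,
                         "nes": np.nan, "p_emp": np.nan, "significant": False,
                         "mode": mode, "skipped": True})
            continue
        es = enrichment_score(ranked, members, H)
        if mode == "gene_shuffle":
            if independent_substreams:
                rng = np.random.default_rng(
                    np.random.SeedSequence(entropy=(seed, rank_of[sid])))
            else:
                rng = np.random.default_rng(np.random.SeedSequence(seed))
            null = gsea_null(len(members), n_perm, mode, rng, ranked=ranked, H=H)
        else:
            null = null_cache[sid]
        nes, p = nes_and_p(es, null, n_perm)
        rows.append({"set_id": sid, "n_members_scored": len(members), "es": es,
                     "nes": nes, "p_emp": p, "significant": p < alpha,
                     "mode": mode, "skipped": False})
    return pd.DataFrame(rows)
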