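"""Per-gene cis-SNP weight models.

Trains predictive models of a molecular trait (protein abundance, expression)
from standardized cis dosages, estimates cis heritability with a
Haseman-Elston moment estimator, and keeps the best model by cross-validated
R^2 — mirroring the multi-model design of summary-statistic TWAS toolkits.
The Bayesian sparse linear mixed model used by the source weight panels is
surrogated by a small Gibbs spike-and-slab sampler (``spike_slab``); it is a
surrogate estimator with the same sparse-plus-polygenic flavour, not a
re-implementation of the original MCMC software.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.linear_model import ElasticNetCV
from sklearn.model_selection import KFold

from .errors import XwasError
from .panel import ReferencePanel

logger = logging.getLogger(__name__)

METHOD_PRECEDENCE = ("spike_slab", "elastic_net", "ridge_blup", "top1")
VALID_METHODS = frozenset(METHOD_PRECEDENCE)


@dataclass
class H2Estimate:
    """Cis-heritability estimate with its pre-truncation value retained."""

    h2_raw: float
    h2_est: float  # clipped to [0, 1]
    h2_p: float
    truncated: bool


def estimate_cis_h2(panel: ReferencePanel, trait, cis_snps) -> H2Estimate:
    """Haseman-Elston moment estimator of cis heritability.

    Regresses off-diagonal trait cross-products ``y_i * y_j`` on the cis
    genetic relatedness ``K_ij`` (K = XX'/m over standardized dosages); the
    slope estimates h2 and its one-sided P comes from the asymptotic normal of
    the no-intercept OLS slope.  Under the null the cross-products are
    pairwise uncorrelated, so the OLS standard error is calibrated there.
    """
    if panel.n_individuals < 10:
        raise XwasError("heritability estimator needs at least 10 individuals")
    cis_snps = list(cis_snps)
    if len(cis_snps) < 2:
        raise XwasError("need at least 2 cis SNPs for heritability estimation")
    y = np.asarray(trait, dtype=float)
    y = (y - y.mean()) / y.std()
    X = panel.standardized(cis_snps)
    K = X @ X.T / X.shape[1]
    iu = np.triu_indices(panel.n_individuals, k=1)
    k = K[iu]
    prod = np.outer(y, y)[iu]
    sxx = float(k @ k)
    slope = float(k @ prod) / sxx
    resid = prod - slope * k
    se = np.sqrt(float(resid @ resid) / (len(k) - 1) / sxx)
    p = float(sps.norm.sf(slope / se))
    h2 = min(max(slope, 0.0), 1.0)
    return H2Estimate(h2_raw=slope, h2_est=h2, h2_p=p, truncated=h2 != slope)


# ----------------------------------------------------------------------
# Individual estimators (all on standardized dosages / standardized trait)
# ----------------------------------------------------------------------

def _fit_top1(X: np.ndarray, y: np.ndarray, **_) -> np.ndarray:
    """Single best marginal SNP: weight = its marginal standardized beta."""
    n = X.shape[0]
    betas = X.T @ y / n
    j = int(np.argmax(np.abs(betas)))
    w = np.zeros(X.shape[1])
    w[j] = betas[j]
    return w


def _fit_ridge(X: np.ndarray, y: np.ndarray, *, ridge_penalty: float, **_) -> np.ndarray:
    """BLUP-style ridge: (X'X + kappa I)^-1 X'y."""
    m = X.shape[1]
    return np.linalg.solve(X.T @ X + ridge_penalty * np.eye(m), X.T @ y)


def _fit_elastic_net(X: np.ndarray, y: np.ndarray, *, seed: int, **_) -> np.ndarray:
    inner_cv = KFold(n_splits=3, shuffle=True, random_state=seed)
    model = ElasticNetCV(l1_ratio=0.5, alphas=25, cv=inner_cv, max_iter=5000)
    model.fit(X, y)
    return model.coef_


def _fit_spike_slab(X: np.ndarray, y: np.ndarray, *, seed: int,
                    n_iter: int = 400, burn_in: int = 100, **_) -> np.ndarray:
    """Gibbs sampler for y = Xb + e with b_j ~ pi N(0, s_b^2) + (1-pi) d_0.

    Posterior-mean weights; conjugate inverse-gamma updates for the residual
    and slab variances and a Beta update for the inclusion probability.
    """
    rng = np.random.default_rng(seed)
    n, m = X.shape
    xtx = np.einsum("ij,ij->j", X, X)
    beta = np.zeros(m)
    gamma = np.zeros(m, dtype=bool)
    sigma_e2, sigma_b2, pi = 1.0, 0.1, 0.2
    resid = y.copy()
    beta_sum = np.zeros(m)
    kept = 0
    for it in range(n_iter):
        for j in rng.permutation(m):
            resid_j = resid + X[:, j] * beta[j]
            xy = float(X[:, j] @ resid_j)
            var_post = 1.0 / (xtx[j] / sigma_e2 + 1.0 / sigma_b2)
            mean_post = var_post * xy / sigma_e2
            # log Bayes factor for inclusion of SNP j
            log_bf = 0.5 * (np.log(var_post) - np.log(sigma_b2)
                            + mean_post**2 / var_post)
            log_odds = np.log(pi / (1.0 - pi)) + log_bf
            p_incl = 1.0 / (1.0 + np.exp(-np.clip(log_odds, -35, 35)))
            gamma[j] = rng.random() < p_incl
            beta[j] = (mean_post + np.sqrt(var_post) * rng.standard_normal()
                       if gamma[j] else 0.0)
            resid = resid_j - X[:, j] * beta[j]
        k = int(gamma.sum())
        sse = float(resid @ resid)
        sigma_e2 = 1.0 / rng.gamma(1.0 + n / 2.0, 1.0 / (1.0 + sse / 2.0))
        ssb = float(beta @ beta)
        sigma_b2 = 1.0 / rng.gamma(1.0 + k / 2.0, 1.0 / (0.1 + ssb / 2.0))
        pi = rng.beta(1.0 + k, 1.0 + m - k)
        pi = min(max(pi, 1e-3), 1.0 - 1e-3)
        if it >= burn_in:
            beta_sum += beta
            kept += 1
    return beta_sum / kept


_FITTERS = {
    "top1": _fit_top1,
    "ridge_blup": _fit_ridge,
    "elastic_net": _fit_elastic_net,
    "spike_slab": _fit_spike_slab,
}


@dataclass
class GeneWeights:
    """Fitted cis-SNP weight vector with fit metadata.

    Weights are on the standardized-dosage scale (trait SD per SD of dosage);
    per-SNP MAF is retained for conversion to the allele-count scale.
    """

    gene_id: str
    chrom: str
    snp_ids: list[str]
    pos: list[int]
    a1: list[str]
    a2: list[str]
    maf: list[float]
    W: np.ndarray
    model_tag: str
    cv_r2: float
    h2_est: float
    h2_raw: float
    h2_p: float
    cv_r2_by_method: dict = field(default_factory=dict)
    predictive: bool = True

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        if len(self.W) != len(self.snp_ids):
            raise XwasError("W length does not match snp_ids")
        if not np.any(self.W != 0):
            raise XwasError("weight vector has no nonzero entry")
        if self.model_tag not in VALID_METHODS:
            raise XwasError(f"unknown model_tag {self.model_tag!r}")
        if not (-1.0 <= self.cv_r2 <= 1.0):
            raise XwasError("cv_r2 outside [-1, 1]")


def _cv_r2(X: np.ndarray, y: np.ndarray, fitter, fold_ids: np.ndarray,
           **kwargs) -> float:
    preds = np.empty_like(y)
    for fold in np.unique(fold_ids):
        test = fold_ids == fold
        w = fitter(X[~test], y[~test], **kwargs)
        preds[test] = X[test] @ w
    ss_res = float(np.sum((y - preds) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    return float(np.clip(1.0 - ss_res / ss_tot, -1.0, 1.0))


def default_ridge_penalty(m_snps: int, h2: float) -> float:
    """BLUP-motivated shrinkage m * (1 - h2) / h2, with h2 kept off the boundary."""
    h2 = min(max(h2, 0.01), 0.99)
    return m_snps * (1.0 - h2) / h2


def fit_weight_models(panel: ReferencePanel, trait, cis_snps,
                      methods=METHOD_PRECEDENCE, cv_folds: int = 5, seed: int = 0,
                      *, gene_id: str = "gene", ridge_penalty=None,
                      h2: H2Estimate | None = None) -> GeneWeights:
    """Fit each requested estimator, score by K-fold CV, keep the best.

    Ties in cv_r2 are broken by the fixed precedence spike_slab > elastic_net >
    ridge_blup > top1.  A gene whose best cv_r2 is <= 0 is flagged
    ``predictive=False`` (and excluded downstream); its top-marginal weights
    are still recorded so the object remains well formed.
    """
    methods = tuple(methods)
    unknown = set(methods) - VALID_METHODS
    if unknown:
        raise XwasError(f"unknown methods: {sorted(unknown)}")
    if cv_folds < 2:
        raise XwasError("cv_folds must be >= 2")
    cis_snps = list(cis_snps)
    X = panel.standardized(cis_snps)
    y = np.asarray(trait, dtype=float)
    y = (y - y.mean()) / y.std()
    if h2 is None:
        h2 = estimate_cis_h2(panel, y, cis_snps)
    if ridge_penalty is None:
        ridge_penalty = default_ridge_penalty(len(cis_snps), h2.h2_est)
    kwargs = {"seed": seed, "ridge_penalty": ridge_penalty}
    fold_ids = np.empty(len(y), dtype=int)
    splitter = KFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    for fold, (_, test) in enumerate(splitter.split(y)):
        fold_ids[test] = fold
    cv_scores: dict[str, float] = {}
    fitted: dict[str, np.ndarray] = {}
    for method in methods:
        fitter = _FITTERS[method]
        cv_scores[method] = _cv_r2(X, y, fitter, fold_ids, **kwargs)
        fitted[method] = fitter(X, y, **kwargs)
    best = max(methods, key=lambda mth: (cv_scores[mth], -METHOD_PRECEDENCE.index(mth)))
    W = fitted[best]
    predictive = cv_scores[best] > 0 and bool(np.any(W != 0))
    if not np.any(W != 0):  # keep the object well formed for bookkeeping
        best_fallback = "top1"
        W = _fit_top1(X, y)
        logger.info("gene %s: %s weights all zero; recording top1 weights "
                    "(flagged non-predictive)", gene_id, best)
        best = best_fallback
    idx = panel.snp_indices(cis_snps)
    meta = panel.snps.iloc[idx]
    return GeneWeights(
        gene_id=gene_id, chrom=str(meta["chrom"].iloc[0]), snp_ids=cis_snps,
        pos=meta["pos"].tolist(), a1=meta["a1"].tolist(), a2=meta["a2"].tolist(),
        maf=meta["maf"].tolist(), W=W, model_tag=best, cv_r2=cv_scores[best]
        if best in cv_scores else -1.0, h2_est=h2.h2_est, h2_raw=h2.h2_raw,
        h2_p=h2.h2_p, cv_r2_by_method=dict(cv_scores), predictive=predictive,
    )


def filter_heritable(genes, alpha_h2: float = 0.01):
    """Keep genes whose cis-heritability test P is below ``alpha_h2``."""
    retained = [g for g in genes if g.h2_p < alpha_h2]
    logger.info("heritability filter: retained %d / %d genes at alpha = %g",
                len(retained), len(list(genes)), alpha_h2)
    return retained


def marginal_qtl_scan(panel: ReferencePanel, trait, cis_snps) -> pd.DataFrame:
    """Per-SNP marginal regressions of the standardized trait on dosage.

    This is how pQTL/eQTL summary statistics arise; the output uses the GWAS
    summary dialect plus ``beta``, ``se`` and ``n`` columns, ready for
    colocalization.
    """
    cis_snps = list(cis_snps)
    X = panel.standardized(cis_snps)
    y = np.asarray(trait, dtype=float)
    y = (y - y.mean()) / y.std()
    n = len(y)
    r = X.T @ y / n
    r = np.clip(r, -0.999999, 0.999999)
    se = np.sqrt((1.0 - r**2) / (n - 2))
    idx = panel.snp_indices(cis_snps)
    out = panel.snps.iloc[idx][["snp_id", "chrom", "pos", "a1", "a2", "maf"]].copy()
    out["beta"] = r
    out["se"] = se
    out["z"] = r / se
    out["n"] = n
    return out.reset_index(drop=True)
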