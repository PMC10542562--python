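"""Mixed-linear-model association with permutation thresholds and jitter filtering.

The stage mirrors a sparse-GRM mixed-model GWAS on an ordinal phenotype:

1. keep biallelic sites with minor allele frequency >= 0.05 (inclusive);
2. greedily prune sites in linkage disequilibrium (pairwise dosage r^2 >
   0.5) in sliding windows;
3. estimate a genetic relationship matrix (GRM) from standardized dosages
   of the pruned sites and sparsify it by zeroing off-diagonal entries
   below 0.05;
4. fit y = mu + g + e with cov(g) = sg^2 * K (K the sparse GRM) and
   cov(e) = se^2 * I, variance components by Haseman-Elston regression,
   then score-test each site by generalized least squares (chi^2, 1 df);
5. set the family-wise significance threshold as the 0.05 quantile of the
   minimum p-value over 1,000 phenotype permutations;
6. filter fragile peaks: re-test 100 jittered phenotype replicates
   (y + N(0, 0.25^2) on the normalized 0-3 scale) and keep only sites
   significant in at least 70% of them.

All heavy paths are vectorized over replicate phenotype vectors: the GRM is
eigendecomposed once, after which every replicate's generalized least
squares reduces to diagonally weighted sums in the rotated basis, with
variance components re-estimated per replicate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .types import GRM, GenotypeMatrix
from ._rng import child_rng

__all__ = [
    "AssocConfig",
    "filter_maf",
    "ld_prune",
    "compute_grm",
    "sparsify_grm",
    "MLMEngine",
    "mlm_assoc",
    "permutation_threshold",
    "jitter_replicates",
    "jitter_robustness",
    "run_association",
]


@dataclass
class AssocConfig:
    """Tuning knobs of the association stage (defaults follow the survey design)."""

    maf_min: float = 0.05
    ld_r2_max: float = 0.5
    ld_window: int = 50
    ld_step: int = 5
    sparse_threshold: float = 0.05
    n_perm: int = 1000
    perm_quantile: float = 0.05
    n_jitter: int = 100
    jitter_sd: float = 0.25
    retention: float = 0.70
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("maf_min", "ld_r2_max", "sparse_threshold", "perm_quantile", "retention"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name}={v} must be in (0,1)")
        for name in ("ld_window", "ld_step", "n_perm", "n_jitter"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be >= 0")


def filter_maf(gm: GenotypeMatrix, maf_min: float = 0.05) -> GenotypeMatrix:
    """Retain sites with minor allele frequency >= maf_min (inclusive)."""
    keep = np.where(gm.minor_allele_freqs() >= maf_min)[0]
    return gm.subset_sites(keep)


def ld_prune(
    gm: GenotypeMatrix,
    r2_max: float = 0.5,
    window: int = 50,
    step: int = 5,
) -> np.ndarray:
    """Greedy sliding-window LD pruning; returns retained site indices.

    Within each window, sites are considered in order of decreasing MAF
    (ties broken by ascending index) and a site is kept only if its
    squared dosage correlation with every already-kept site in the window
    is <= r2_max. Deterministic given the input order.
    """
    m = gm.n_sites
    if m == 0:
        return np.array([], dtype=int)
    maf = gm.minor_allele_freqs()
    X = gm.imputed()
    removed = np.zeros(m, dtype=bool)
    starts = range(0, max(m - window, 0) + 1, step) if m > window else [0]
    for start in starts:
        idx = [i for i in range(start, min(start + window, m)) if not removed[i]]
        if len(idx) < 2:
            continue
        with np.errstate(invalid="ignore", divide="ignore"):
            r2 = np.corrcoef(X[:, idx], rowvar=False) ** 2
        r2 = np.nan_to_num(r2, nan=0.0)
        order = sorted(range(len(idx)), key=lambda k: (-maf[idx[k]], idx[k]))
        kept_local: list[int] = []
        for k in order:
            if any(r2[k, j] > r2_max for j in kept_local):
                removed[idx[k]] = True
            else:
                kept_local.append(k)
    return np.where(~removed)[0]


def compute_grm(gm: GenotypeMatrix) -> GRM:
    """GRM from standardized dosages: (1/m) sum_i (x_ij-2p_i)(x_ik-2p_i)/(2p_i(1-p_i)).

    Sample allele frequencies; missing dosages mean-imputed; monomorphic
    sites carry no information and are excluded with a warning.
    """
    X = gm.imputed()
    p = X.mean(axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    if not poly.all():
        warnings.warn(
            f"excluding {int((~poly).sum())} monomorphic site(s) from the GRM",
            stacklevel=2,
        )
    X = X[:, poly]
    p = p[poly]
    if X.shape[1] == 0:
        raise ValueError("no polymorphic sites available for the GRM")
    Z = (X - 2 * p) / np.sqrt(2 * p * (1 - p))
    K = Z @ Z.T / Z.shape[1]
    K = (K + K.T) / 2.0
    return GRM(strain_ids=list(gm.strain_ids), values=K)


def sparsify_grm(grm: GRM, threshold: float = 0.05) -> GRM:
    """Zero off-diagonal entries below threshold; diagonal untouched."""
    K = grm.values.copy()
    off = ~np.eye(K.shape[0], dtype=bool)
    K[off & (K < threshold)] = 0.0
    return GRM(
        strain_ids=list(grm.strain_ids),
        values=K,
        sparse_threshold_applied=threshold,
    )


class MLMEngine:
    """Batched mixed-model score tests against a fixed relationship matrix.

    Eigendecomposes K once; for each phenotype column, Haseman-Elston
    regression gives (sg^2, se^2), and the GLS score test for every site
    is computed with diagonal weights in the rotated basis. Handles many
    phenotype replicates (permutations, jitters) in one pass.
    """

    def __init__(self, K: np.ndarray):
        K = np.asarray(K, dtype=float)
        self.n = K.shape[0]
        self.K = K
        self.evals, self.U = np.linalg.eigh(K)
        self.evals = np.clip(self.evals, 0.0, None)  # PSD up to round-off
        # HE regression denominator: sum of squared off-diagonal entries
        self._he_denom = (K**2).sum() - (np.diag(K) ** 2).sum()
        self._diag_mean = float(np.diag(K).mean())
        self._ones_rot = self.U.T @ np.ones(self.n)

    def he_components(self, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Haseman-Elston variance components per phenotype column.

        Regresses pairwise phenotype cross-products on the corresponding
        GRM entries: sg^2 = sum_{j!=k} K_jk y_j y_k / sum_{j!=k} K_jk^2,
        clamped to [0, var(y)]; se^2 is the remainder of the variance.
        """
        Yc = Y - Y.mean(axis=0, keepdims=True)
        tot_var = (Yc**2).mean(axis=0)
        if self._he_denom <= 0:
            sg = np.zeros(Y.shape[1])
        else:
            num = (Yc * (self.K @ Yc)).sum(axis=0) - np.diag(self.K) @ (Yc**2)
            sg = np.clip(num / self._he_denom, 0.0, None)
        sg = np.minimum(sg, np.where(self._diag_mean > 0, tot_var / max(self._diag_mean, 1e-12), np.inf))
        se = tot_var - sg * self._diag_mean
        floor = np.maximum(1e-8 * np.where(tot_var > 0, tot_var, 1.0), 1e-12)
        if np.any(se < floor):
            se = np.maximum(se, floor)
        return sg, se

    def score_tests(
        self, X: np.ndarray, Y: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-site GLS score tests for each phenotype column.

        Parameters: X dosages (n x m), Y phenotypes (n x B). Returns
        (chi2, beta, se_beta) arrays of shape (m, B); p-values follow as
        chi2_1 survival probabilities.
        """
        X = np.asarray(X, dtype=float)
        Y = np.asarray(Y, dtype=float)
        if Y.ndim == 1:
            Y = Y[:, None]
        sg, se = self.he_components(Y)
        # Per-column inverse-variance weights in the eigenbasis of K.
        W = 1.0 / (np.outer(self.evals, sg) + se[None, :])  # n x B
        Xr = self.U.T @ X  # n x m
        Yr = self.U.T @ Y  # n x B
        o = self._ones_rot  # n
        S11 = (o**2) @ W  # B
        S1y = (o[:, None] * W * Yr).sum(axis=0)  # B
        Sxy = Xr.T @ (W * Yr)  # m x B
        Sx1 = Xr.T @ (W * o[:, None])  # m x B
        Sxx = (Xr**2).T @ W  # m x B
        U_score = Sxy - Sx1 * (S1y / S11)[None, :]
        VarU = Sxx - Sx1**2 / S11[None, :]
        VarU = np.maximum(VarU, 1e-300)
        chi2 = U_score**2 / VarU
        beta = U_score / VarU
        se_beta = 1.0 / np.sqrt(VarU)
        return chi2, beta, se_beta

    def pvalues(self, X: np.ndarray, Y: np.ndarray) -> np.ndarray:
        chi2, _, _ = self.score_tests(X, Y)
        return stats.chi2.sf(chi2, df=1)


def _engine_for(gm: GenotypeMatrix, grm: GRM) -> tuple[MLMEngine, np.ndarray]:
    if list(grm.strain_ids) != list(gm.strain_ids):
        raise ValueError("GRM and genotype matrix strain order disagree")
    return MLMEngine(grm.values), gm.imputed()


def mlm_assoc(gm: GenotypeMatrix, y: np.ndarray, grm: GRM) -> pd.DataFrame:
    """Mixed-model score test for every site against one phenotype vector.

    Returns a frame with site_id, effect, std_err, p_value.
    """
    y = np.asarray(y, dtype=float)
    if y.shape[0] != gm.n_strains:
        raise ValueError("phenotype length does not match strain count")
    engine, X = _engine_for(gm, grm)
    chi2, beta, se_beta = engine.score_tests(X, y)
    p = stats.chi2.sf(chi2[:, 0], df=1)
    return pd.DataFrame(
        {
            "site_id": gm.site_ids,
            "effect": beta[:, 0],
            "std_err": se_beta[:, 0],
            "p_value": p,
        }
    )


def permutation_threshold(
    gm: GenotypeMatrix,
    y: np.ndarray,
    grm: GRM,
    cfg: AssocConfig | None = None,
) -> float:
    """Family-wise p-value threshold from the permutation min-p distribution.

    Permutes the phenotype across strains (breaking both the genotype and
    relatedness links), refits the mixed model per permutation, records
    the genome-wide minimum p, and returns its ``perm_quantile`` quantile.
    """
    cfg = cfg or AssocConfig()
    if cfg.n_perm < 20:
        warnings.warn("fewer than 20 permutations: quantile estimate is unstable", stacklevel=2)
    rng = child_rng(cfg.seed, "permutation_threshold")
    y = np.asarray(y, dtype=float)
    engine, X = _engine_for(gm, grm)
    perms = np.stack([rng.permutation(y) for _ in range(cfg.n_perm)], axis=1)
    P = engine.pvalues(X, perms)  # m x n_perm
    min_p = P.min(axis=0)
    return float(np.quantile(min_p, cfg.perm_quantile))


def jitter_replicates(y: np.ndarray, cfg: AssocConfig | None = None) -> np.ndarray:
    """The matrix of jittered phenotype replicates (n x n_jitter).

    Each column is y + N(0, jitter_sd^2) elementwise, drawn from the
    stage's seeded generator; exposed so the within/between-class rank
    behaviour of the jitter can be examined directly.
    """
    cfg = cfg or AssocConfig()
    rng = child_rng(cfg.seed, "jitter_robustness")
    y = np.asarray(y, dtype=float)
    if cfg.jitter_sd > 0:
        noise = rng.normal(0.0, cfg.jitter_sd, size=(y.shape[0], cfg.n_jitter))
    else:
        noise = np.zeros((y.shape[0], cfg.n_jitter))
    return y[:, None] + noise


def jitter_robustness(
    gm: GenotypeMatrix,
    y: np.ndarray,
    grm: GRM,
    threshold: float,
    cfg: AssocConfig | None = None,
) -> pd.DataFrame:
    """Per-site significance retention across jittered phenotype replicates.

    Each replicate adds N(0, jitter_sd^2) noise elementwise (randomizing
    rank order within ordinal classes while essentially preserving it
    between classes) and refits the mixed model. ``jitter_fraction`` is
    the proportion of replicates with p <= threshold; a site is robust
    when that fraction reaches ``retention``.
    """
    cfg = cfg or AssocConfig()
    engine, X = _engine_for(gm, grm)
    Y = jitter_replicates(y, cfg)
    P = engine.pvalues(X, Y)  # m x n_jitter
    frac = (P <= threshold).mean(axis=1)
    return pd.DataFrame(
        {
            "site_id": gm.site_ids,
            "jitter_fraction": frac,
            "robust": frac >= cfg.retention,
        }
    )


def run_association(
    gm: GenotypeMatrix,
    y: np.ndarray,
    cfg: AssocConfig | None = None,
    grm: GRM | None = None,
) -> tuple[pd.DataFrame, float]:
    """Full association stage; returns (per-site results, p threshold).

    MAF filtering is applied first; the GRM is estimated from LD-pruned
    sites (then sparsified) unless a precomputed GRM is supplied; all
    MAF-passing sites are then tested.
    """
    cfg = cfg or AssocConfig()
    gm = filter_maf(gm, cfg.maf_min)
    if gm.n_sites == 0:
        raise ValueError("no sites pass the MAF filter")
    if grm is None:
        kept = ld_prune(gm, cfg.ld_r2_max, cfg.ld_window, cfg.ld_step)
        grm = sparsify_grm(compute_grm(gm.subset_sites(kept)), cfg.sparse_threshold)
    results = mlm_assoc(gm, y, grm)
    threshold = permutation_threshold(gm, y, grm, cfg)
    results["passes_threshold"] = results["p_value"] <= threshold
    jit = jitter_robustness(gm, y, grm, threshold, cfg)
    results = results.merge(jit, on="site_id")
    return results, threshold
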