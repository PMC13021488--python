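"""Phenotype preparation, genotype QC, principal components, discovery GWAS.

Blood-pressure readings of treated individuals are adjusted upward by the
standard fixed increments (+15 mmHg systolic, +10 mmHg diastolic) before any
trait derivation or association testing; hypertension status, by contrast,
is defined on the raw readings (SBP >= 140, DBP >= 90, or medication use).
The per-SNP association model is ordinary least squares of the adjusted
trait on allele dosage with age, sex and the top genetic principal
components as covariates; effect sizes are oriented to the trait-increasing
(risk) allele.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

TRAITS = ("sbp", "dbp", "map", "pp")

MED_ADJUST_SBP = 15.0
MED_ADJUST_DBP = 10.0
HTN_SBP_THRESHOLD = 140.0
HTN_DBP_THRESHOLD = 90.0


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------

def adjust_medication(sbp_raw, dbp_raw, med_use):
    """Add +15/+10 mmHg to the SBP/DBP of individuals on medication.

    ``med_use`` must be fully observed (no NaN): the adjustment is not
    silently skipped for individuals of unknown treatment status.
    """
    sbp = np.asarray(sbp_raw, dtype=np.float64)
    dbp = np.asarray(dbp_raw, dtype=np.float64)
    med = np.asarray(med_use, dtype=np.float64)
    if np.isnan(med).any():
        raise ValueError("med_use contains missing values; cannot adjust")
    if (sbp <= 0).any() or (dbp <= 0).any():
        raise ValueError("blood-pressure values must be positive")
    return sbp + MED_ADJUST_SBP * med, dbp + MED_ADJUST_DBP * med


def derive_traits(sbp_adj, dbp_adj):
    """Pulse pressure and mean arterial pressure from (adjusted) SBP/DBP.

    PP = SBP - DBP;  MAP = (SBP + 2 DBP) / 3 (standard clinical formulas).
    """
    sbp = np.asarray(sbp_adj, dtype=np.float64)
    dbp = np.asarray(dbp_adj, dtype=np.float64)
    return sbp - dbp, (sbp + 2.0 * dbp) / 3.0


def classify_hypertension(sbp_raw, dbp_raw, med_use):
    """Hypertension status: raw SBP >= 140, raw DBP >= 90, or on medication."""
    sbp = np.asarray(sbp_raw, dtype=np.float64)
    dbp = np.asarray(dbp_raw, dtype=np.float64)
    med = np.asarray(med_use)
    return (
        (sbp >= HTN_SBP_THRESHOLD) | (dbp >= HTN_DBP_THRESHOLD) | (med == 1)
    ).astype(np.int64)


def prepare_phenotypes(phen: pd.DataFrame) -> pd.DataFrame:
    """Full phenotype table: adjusted traits, derived traits, HTN status.

    Expects columns sample_id, sbp, dbp, age, sex, med_use; adds sbp_adj,
    dbp_adj, pp_adj, map_adj, htn.  Negative pulse pressure is flagged with
    a warning but kept.
    """
    out = phen.copy()
    sbp_adj, dbp_adj = adjust_medication(out["sbp"], out["dbp"], out["med_use"])
    pp, map_ = derive_traits(sbp_adj, dbp_adj)
    out["sbp_adj"], out["dbp_adj"] = sbp_adj, dbp_adj
    out["pp_adj"], out["map_adj"] = pp, map_
    out["htn"] = classify_hypertension(out["sbp"], out["dbp"], out["med_use"])
    n_neg = int((pp < 0).sum())
    if n_neg:
        logger.warning("prepare_phenotypes: %d individual(s) with negative PP", n_neg)
    return out


def trait_column(trait: str) -> str:
    if trait not in TRAITS:
        raise ValueError(f"unknown trait {trait!r}; expected one of {TRAITS}")
    return f"{trait}_adj"


# ---------------------------------------------------------------------------
# genotype QC
# ---------------------------------------------------------------------------

def hwe_exact_p(n_het: int, n_hom1: int, n_hom2: int) -> float:
    """Exact Hardy-Weinberg equilibrium test p-value (biallelic SNP).

    Sums the probabilities of all heterozygote counts no more likely than
    the observed one, conditional on the allele counts (the standard exact
    test on genotype counts).
    """
    n = n_het + n_hom1 + n_hom2
    if n == 0:
        return 1.0
    rare = 2 * min(n_hom1, n_hom2) + n_het
    # probability of each possible heterozygote count via the recurrence
    het_max = rare if (rare % 2 == n_het % 2) else rare - 1
    probs = {}
    mid = rare * (2 * n - rare) // (2 * n)  # mode region start
    if mid % 2 != rare % 2:
        mid += 1
    probs[mid] = 1.0
    h = mid
    while h >= 2:
        hom_r = (rare - h) // 2
        hom_c = n - h - hom_r
        probs[h - 2] = probs[h] * h * (h - 1) / (4.0 * (hom_r + 1) * (hom_c + 1))
        h -= 2
    h = mid
    while h + 2 <= het_max:
        hom_r = (rare - h) // 2
        hom_c = n - h - hom_r
        probs[h + 2] = probs[h] * 4.0 * hom_r * hom_c / ((h + 2) * (h + 1))
        h += 2
    total = sum(probs.values())
    p_obs = probs.get(n_het, 0.0)
    p = sum(v for v in probs.values() if v <= p_obs * (1 + 1e-12)) / total
    return min(1.0, p)


@dataclass
class FilterLog:
    n_input: int
    n_maf: int
    n_missing: int
    n_hwe: int
    n_retained: int


def qc_filter(
    variants: pd.DataFrame,
    dosages: np.ndarray,
    maf_min: float = 0.05,
    miss_max: float = 0.05,
    hwe_alpha: float = 1e-6,
) -> tuple[pd.DataFrame, np.ndarray, FilterLog]:
    """Drop SNPs failing MAF, missingness, or HWE exact-test thresholds.

    MAF < ``maf_min`` is excluded (MAF exactly at the threshold is kept);
    HWE is tested on hard genotypes only (rounded dosages).  Raises when no
    SNP survives.
    """
    m = dosages.shape[1]
    miss = np.isnan(dosages).mean(axis=0)
    with np.errstate(invalid="ignore"):
        freq = np.nanmean(dosages, axis=0) / 2.0
    maf = np.minimum(freq, 1.0 - freq)
    maf = np.where(np.isnan(maf), 0.0, maf)
    fail_maf = maf < maf_min
    fail_miss = miss > miss_max
    fail_hwe = np.zeros(m, dtype=bool)
    hard = np.rint(dosages)
    for j in range(m):
        if fail_maf[j] or fail_miss[j]:
            continue
        col = hard[:, j]
        col = col[~np.isnan(col)]
        n_het = int((col == 1).sum())
        n_hom_alt = int((col == 2).sum())
        n_hom_ref = int((col == 0).sum())
        if hwe_exact_p(n_het, n_hom_ref, n_hom_alt) < hwe_alpha:
            fail_hwe[j] = True
    keep = ~(fail_maf | fail_miss | fail_hwe)
    if not keep.any():
        raise ValueError("qc_filter removed every SNP")
    log = FilterLog(
        n_input=m,
        n_maf=int(fail_maf.sum()),
        n_missing=int(fail_miss.sum()),
        n_hwe=int(fail_hwe.sum()),
        n_retained=int(keep.sum()),
    )
    logger.info(
        "qc_filter: %d -> %d SNPs (MAF %d, missingness %d, HWE %d)",
        log.n_input, log.n_retained, log.n_maf, log.n_missing, log.n_hwe,
    )
    return variants.loc[keep].reset_index(drop=True), dosages[:, keep], log


# ---------------------------------------------------------------------------
# principal components
# ---------------------------------------------------------------------------

def _ld_prune_indices(
    dosages: np.ndarray, pos: np.ndarray, r2_max: float, window_bp: int
) -> np.ndarray:
    """Greedy positional LD pruning on dosage correlations (left to right)."""
    m = dosages.shape[1]
    sd = dosages.std(axis=0)
    keep: list[int] = []
    for j in range(m):
        if sd[j] == 0:
            continue
        ok = True
        for k in reversed(keep):
            if pos[j] - pos[k] > window_bp:
                break
            r = np.corrcoef(dosages[:, j], dosages[:, k])[0, 1]
            if r * r > r2_max:
                ok = False
                break
        if ok:
            keep.append(j)
    return np.array(keep, dtype=np.intp)


def compute_pcs(
    dosages: np.ndarray,
    k: int = 5,
    variants: pd.DataFrame | None = None,
    ld_prune: bool = True,
    prune_r2: float = 0.2,
    prune_window_bp: int = 250_000,
) -> np.ndarray:
    """Top-``k`` genetic principal components of column-standardized dosages.

    Zero-variance columns are dropped; when ``variants`` is given, SNPs are
    greedily LD-pruned (r^2 < ``prune_r2`` within ``prune_window_bp``) before
    the decomposition to keep the axes from locking onto single LD blocks.
    Scores use a deterministic sign convention (the largest-magnitude score
    of each axis is positive) and are standardized to unit variance; columns
    are mutually orthogonal.
    """
    X = np.asarray(dosages, dtype=np.float64)
    n = X.shape[0]
    if n < k + 1:
        raise ValueError(f"need at least k+1={k + 1} individuals for {k} PCs")
    col_mean = np.nanmean(X, axis=0)
    X = np.where(np.isnan(X), col_mean, X)
    if ld_prune and variants is not None:
        idx = _ld_prune_indices(
            X, variants["pos"].to_numpy(), prune_r2, prune_window_bp
        )
        X = X[:, idx]
    sd = X.std(axis=0)
    keep = sd > 0
    X = (X[:, keep] - X[:, keep].mean(axis=0)) / X[:, keep].std(axis=0)
    rank = min(X.shape)
    if k > rank:
        raise ValueError(f"k={k} exceeds matrix rank {rank}")
    U, S, _ = np.linalg.svd(X, full_matrices=False)
    scores = U[:, :k] * S[:k]
    for j in range(k):
        if scores[np.argmax(np.abs(scores[:, j])), j] < 0:
            scores[:, j] = -scores[:, j]
    return scores / scores.std(axis=0)


def covariate_matrix(phen: pd.DataFrame, pcs: np.ndarray) -> pd.DataFrame:
    """Age, sex and PC covariates, indexed like ``phen``."""
    cov = pd.DataFrame(
        {"age": phen["age"].to_numpy(), "sex": phen["sex"].to_numpy()},
        index=phen.index,
    )
    for j in range(pcs.shape[1]):
        cov[f"pc{j + 1}"] = pcs[:, j]
    return cov


# ---------------------------------------------------------------------------
# GWAS
# ---------------------------------------------------------------------------

def gwas_additive(
    dosages: np.ndarray,
    trait_values,
    covariates: pd.DataFrame,
    variants: pd.DataFrame,
) -> pd.DataFrame:
    """Per-SNP additive linear model of an adjusted trait on allele dosage.

    Each SNP is tested by OLS of trait on dosage plus intercept and
    covariates; two-sided p-values use the t reference with
    ``n_used - (n_covariates + 2)`` degrees of freedom.  Effects are
    oriented to the trait-increasing allele: ``risk_allele`` is ALT when the
    ALT-dosage coefficient is non-negative and REF otherwise, and ``beta``
    is reported >= 0 (orientation leaves the p-value unchanged).  SNPs with
    zero dosage variance are skipped with a log entry; missing dosages are
    handled per SNP by complete-case analysis.
    """
    y = np.asarray(trait_values, dtype=np.float64)
    Z = np.column_stack([np.ones(len(y)), covariates.to_numpy(dtype=np.float64)])
    if np.isnan(y).any() or np.isnan(Z).any():
        keep = ~(np.isnan(y) | np.isnan(Z).any(axis=1))
        y, Z = y[keep], Z[keep]
        dosages = dosages[keep]
    n, p_cov = Z.shape
    if np.linalg.matrix_rank(Z) < p_cov:
        raise ValueError("collinear covariates (design matrix rank-deficient)")
    # residualize once against covariates (Frisch-Waugh-Lovell)
    Q, _ = np.linalg.qr(Z)

    def residualize(v: np.ndarray) -> np.ndarray:
        return v - Q @ (Q.T @ v)

    y_res = residualize(y)
    m = dosages.shape[1]
    has_nan = np.isnan(dosages).any(axis=0)
    beta = np.full(m, np.nan)
    se = np.full(m, np.nan)
    pval = np.full(m, np.nan)
    n_used = np.zeros(m, dtype=np.int64)
    skipped = 0
    df_full = n - (p_cov + 1)

    clean = np.flatnonzero(~has_nan)
    if clean.size:
        D = dosages[:, clean]
        D_res = D - Q @ (Q.T @ D)
        xx = (D_res**2).sum(axis=0)
        ok = xx > 1e-12
        xy = D_res.T @ y_res
        b = np.where(ok, xy / np.where(ok, xx, 1.0), np.nan)
        rss = (y_res**2).sum() - b**2 * xx
        sigma2 = rss / df_full
        s = np.sqrt(np.where(ok, sigma2 / np.where(ok, xx, 1.0), np.nan))
        t = b / s
        beta[clean] = b
        se[clean] = s
        pval[clean] = 2.0 * stats.t.sf(np.abs(t), df_full)
        n_used[clean] = n
        skipped += int((~ok).sum())
        beta[clean[~ok]] = np.nan

    for j in np.flatnonzero(has_nan):
        d = dosages[:, j]
        mask = ~np.isnan(d)
        nj = int(mask.sum())
        dfj = nj - (p_cov + 1)
        if dfj < 1 or d[mask].std() == 0:
            skipped += 1
            continue
        X = np.column_stack([Z[mask], d[mask]])
        coef, res_ss, rank_, _ = np.linalg.lstsq(X, y[mask], rcond=None)
        resid = y[mask] - X @ coef
        sigma2 = (resid @ resid) / dfj
        XtX_inv = np.linalg.inv(X.T @ X)
        beta[j] = coef[-1]
        se[j] = np.sqrt(sigma2 * XtX_inv[-1, -1])
        pval[j] = 2.0 * stats.t.sf(abs(beta[j] / se[j]), dfj)
        n_used[j] = nj

    if skipped:
        logger.info("gwas_additive: skipped %d zero-variance SNP(s)", skipped)

    out = variants[["snp_id", "chrom", "pos", "ref", "alt"]].copy()
    flip = beta < 0
    out["risk_allele"] = np.where(flip, out["ref"], out["alt"])
    out["other_allele"] = np.where(flip, out["alt"], out["ref"])
    out["beta"] = np.abs(beta)
    out["se"] = se
    out["p"] = pval
    out["n_used"] = n_used
    return out.loc[~np.isnan(beta)].reset_index(drop=True)
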