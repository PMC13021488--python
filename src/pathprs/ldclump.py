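"""LD r^2 from unphased genotypes and greedy p-value-indexed clumping.

Pairwise r^2 is computed from maximum-likelihood two-locus haplotype
frequencies: the only phase ambiguity in unphased biallelic genotypes is the
double heterozygote, which the EM algorithm resolves iteratively.  Clumping
walks the association results in order of ascending p-value; each unassigned
SNP becomes an index SNP and absorbs every unassigned SNP on the same
chromosome within the distance window whose r^2 with it (in the designated
LD reference cohort) exceeds the threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

EM_TOL = 1e-10
EM_MAX_ITER = 1000


@dataclass(frozen=True)
class LdParams:
    """Clumping parameters: distance window, r^2 threshold, reference cohort."""

    window_bp: int = 250_000
    r2_max: float = 0.1
    ref_cohort: str = "validation"

    def __post_init__(self) -> None:
        if self.window_bp <= 0:
            raise ValueError("window_bp must be positive")
        if not (0.0 < self.r2_max < 1.0):
            raise ValueError("r2_max must be in (0, 1)")


@dataclass
class ClumpedSet:
    """Retained index SNPs (in selection order) and their absorbed members."""

    index_snps: pd.DataFrame  # snp_id, chrom, pos, p in selection order
    members: dict[str, list[str]] = field(default_factory=dict)
    n_dropped_missing_ref: int = 0

    @property
    def snp_ids(self) -> list[str]:
        return self.index_snps["snp_id"].tolist()


def _genotype_counts(ga: np.ndarray, gb: np.ndarray) -> np.ndarray:
    """3x3 table of hard-genotype pairs over pairwise-complete observations."""
    if ga.shape != gb.shape:
        raise ValueError("genotype vectors differ in length")
    mask = ~(np.isnan(ga) | np.isnan(gb))
    a = ga[mask]
    b = gb[mask]
    if np.any((a < 0) | (a > 2) | (b < 0) | (b > 2)):
        raise ValueError("genotypes must be in {0, 1, 2}")
    idx = (a * 3 + b).astype(np.intp)
    return np.bincount(idx, minlength=9).reshape(3, 3)


def em_haplotype_freqs(
    counts: np.ndarray, tol: float = EM_TOL, max_iter: int = EM_MAX_ITER
) -> tuple[float, float, float, float]:
    """EM estimates of the four haplotype frequencies (p11, p10, p01, p00).

    ``p_ab`` is the frequency of the haplotype carrying ``a`` ALT alleles at
    the first locus and ``b`` at the second.  Initialized at linkage
    equilibrium; iterates until the largest frequency change is below
    ``tol`` or ``max_iter`` iterations.
    """
    c = np.asarray(counts, dtype=np.float64)
    n = c.sum()
    if n == 0:
        return 0.25, 0.25, 0.25, 0.25
    # haplotype counts fixed by unambiguous genotypes
    f11 = 2 * c[2, 2] + c[2, 1] + c[1, 2]
    f10 = 2 * c[2, 0] + c[2, 1] + c[1, 0]
    f01 = 2 * c[0, 2] + c[1, 2] + c[0, 1]
    f00 = 2 * c[0, 0] + c[0, 1] + c[1, 0]
    ndh = c[1, 1]  # double heterozygotes: phase-ambiguous
    total = 2.0 * n
    pa = (f11 + f10 + ndh) / total
    pb = (f11 + f01 + ndh) / total
    p11, p10 = pa * pb, pa * (1 - pb)
    p01, p00 = (1 - pa) * pb, (1 - pa) * (1 - pb)
    for _ in range(max_iter):
        denom = p11 * p00 + p10 * p01
        q = 0.5 if denom <= 0 else (p11 * p00) / denom
        n11 = (f11 + q * ndh) / total
        n10 = (f10 + (1 - q) * ndh) / total
        n01 = (f01 + (1 - q) * ndh) / total
        n00 = (f00 + q * ndh) / total
        delta = max(
            abs(n11 - p11), abs(n10 - p10), abs(n01 - p01), abs(n00 - p00)
        )
        p11, p10, p01, p00 = n11, n10, n01, n00
        if delta < tol:
            break
    return p11, p10, p01, p00


def em_r2(ga, gb) -> float:
    """LD r^2 between two unphased genotype vectors via haplotype EM.

    ``r^2 = D^2 / (pA qA pB qB)`` with ``D = p11 - pA pB``; returns 0 when
    either SNP is monomorphic in the pairwise-complete subset.
    """
    counts = _genotype_counts(
        np.asarray(ga, dtype=np.float64), np.asarray(gb, dtype=np.float64)
    )
    p11, p10, p01, p00 = em_haplotype_freqs(counts)
    pa = p11 + p10
    pb = p11 + p01
    denom = pa * (1 - pa) * pb * (1 - pb)
    if denom <= 0:
        return 0.0
    d = p11 - pa * pb
    return float(min(1.0, d * d / denom))


def _hard_genotypes(dosages: np.ndarray) -> np.ndarray:
    """Round fractional dosages to hard genotypes (NaN preserved)."""
    hard = np.rint(dosages)
    frac = np.nanmax(np.abs(dosages - hard)) if dosages.size else 0.0
    if frac > 1e-6:
        logger.warning(
            "fractional dosages rounded to hard genotypes for haplotype EM "
            "(max deviation %.3g)", frac,
        )
    return np.clip(hard, 0, 2)


def greedy_clump(
    assoc: pd.DataFrame,
    ref_dosages: np.ndarray,
    ref_variants: pd.DataFrame,
    params: LdParams = LdParams(),
    p_index_max: float = 1.0,
    r2_cache: dict | None = None,
) -> ClumpedSet:
    """Greedy p-value-indexed LD clumping against a reference cohort.

    SNPs are visited in ascending p-value (ties broken by chromosome,
    position, then SNP id); each unassigned SNP is retained as an index and
    absorbs every unassigned SNP on the same chromosome within
    ``params.window_bp`` whose EM r^2 with it exceeds ``params.r2_max``.
    Association SNPs absent from the reference panel are dropped with a
    warning count.  ``r2_cache`` (keyed by SNP-id pairs) lets callers reuse
    r^2 values across traits that share the reference panel.
    """
    ref_col = {sid: j for j, sid in enumerate(ref_variants["snp_id"])}
    df = assoc.loc[assoc["p"] <= p_index_max].copy()
    in_ref = df["snp_id"].map(ref_col).notna()
    n_dropped = int((~in_ref).sum())
    if n_dropped:
        logger.warning(
            "greedy_clump: %d SNP(s) missing from the LD reference dropped",
            n_dropped,
        )
    df = df.loc[in_ref]
    df = df.sort_values(
        ["p", "chrom", "pos", "snp_id"], kind="stable"
    ).reset_index(drop=True)
    hard = _hard_genotypes(ref_dosages)
    cache = r2_cache if r2_cache is not None else {}

    snp_ids = df["snp_id"].to_numpy()
    chroms = df["chrom"].astype(str).to_numpy()
    pos = df["pos"].to_numpy(dtype=np.int64)
    assigned = np.zeros(len(df), dtype=bool)
    index_rows: list[int] = []
    members: dict[str, list[str]] = {}
    for i in range(len(df)):
        if assigned[i]:
            continue
        assigned[i] = True
        index_rows.append(i)
        clumped: list[str] = []
        near = np.flatnonzero(
            (~assigned)
            & (chroms == chroms[i])
            & (np.abs(pos - pos[i]) <= params.window_bp)
        )
        gi = hard[:, ref_col[snp_ids[i]]]
        for j in near:
            key = (snp_ids[i], snp_ids[j]) if snp_ids[i] < snp_ids[j] else (
                snp_ids[j], snp_ids[i]
            )
            r2 = cache.get(key)
            if r2 is None:
                r2 = em_r2(gi, hard[:, ref_col[snp_ids[j]]])
                cache[key] = r2
            if r2 > params.r2_max:
                assigned[j] = True
                clumped.append(snp_ids[j])
        members[snp_ids[i]] = clumped
    index_snps = df.loc[index_rows, ["snp_id", "chrom", "pos", "p"]].reset_index(
        drop=True
    )
    return ClumpedSet(
        index_snps=index_snps, members=members, n_dropped_missing_ref=n_dropped
    )


def clumped_to_frame(clumped: ClumpedSet) -> pd.DataFrame:
    """TSV-ready view: index_snp, p, n_clumped, clumped_snp_ids."""
    rows = [
        (
            r.snp_id,
            r.p,
            len(clumped.members.get(r.snp_id, [])),
            ";".join(clumped.members.get(r.snp_id, [])),
        )
        for r in clumped.index_snps.itertuples()
    ]
    return pd.DataFrame(rows, columns=["index_snp", "p", "n_clumped", "clumped_snp_ids"])
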