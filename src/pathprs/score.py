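"""Clumping-and-thresholding PRS models, scoring, and threshold selection.

A model is the intersection of the clumped index SNPs, a pathway's SNP list,
and the discovery p-value cut-off from the fixed seven-point grid; its
weights are the discovery effect sizes oriented to the risk allele.
Scoring follows PLINK's default semantics: the average weighted risk-allele
dosage, ``score_i = sum_j w_j d_ij / (2 m_i)``, with missing genotypes
mean-imputed from the risk-allele frequency when imputation is on (the
default).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import evaluate as _evaluate
from .ldclump import ClumpedSet

logger = logging.getLogger(__name__)

#: the fixed p-value threshold grid
THRESHOLD_GRID = (0.0010, 0.0025, 0.0050, 0.0075, 0.0100, 0.0250, 0.0500)


@dataclass
class PrsModel:
    trait: str
    pathway_id: str
    threshold: float
    snps: pd.DataFrame  # snp_id, risk_allele, weight
    n_genes: int | None = None

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def is_empty(self) -> bool:
        return self.n_snps == 0


def build_model(
    assoc: pd.DataFrame,
    clumped: ClumpedSet,
    snp_map: dict[str, np.ndarray],
    variants: pd.DataFrame,
    trait: str,
    pathway_id: str,
    threshold: float,
    pathway_set=None,
) -> PrsModel:
    """Clumped index SNPs within the pathway passing the p-value threshold.

    An empty intersection is flagged (logged) but not fatal.  ``n_genes``
    counts the pathway genes whose interval contains at least one model SNP
    and is filled only when ``pathway_set`` is supplied.
    """
    if pathway_id not in snp_map:
        raise KeyError(f"unknown pathway {pathway_id!r}")
    pathway_snps = set(variants["snp_id"].iloc[snp_map[pathway_id]])
    keep = (
        assoc["snp_id"].isin(set(clumped.snp_ids))
        & assoc["snp_id"].isin(pathway_snps)
        & (assoc["p"] <= threshold)
    )
    snps = assoc.loc[keep, ["snp_id", "risk_allele", "beta"]].rename(
        columns={"beta": "weight"}
    ).reset_index(drop=True)
    model = PrsModel(trait=trait, pathway_id=pathway_id, threshold=threshold, snps=snps)
    if model.is_empty:
        logger.info(
            "build_model: empty model (trait=%s pathway=%s threshold=%g)",
            trait, pathway_id, threshold,
        )
    if pathway_set is not None and not model.is_empty:
        pos_by_id = dict(
            zip(assoc.loc[keep, "snp_id"], zip(assoc.loc[keep, "chrom"],
                                               assoc.loc[keep, "pos"]))
        )
        genes_hit = set()
        for gene in (
            pathway_set.combined_genes
            if pathway_id == "combined"
            else pathway_set.genes(pathway_id)
        ):
            for iv in pathway_set.intervals_for(gene):
                for _, (c, p) in pos_by_id.items():
                    if str(c) == str(iv.chrom) and iv.start <= p <= iv.end:
                        genes_hit.add(gene)
                        break
        model.n_genes = len(genes_hit)
    return model


def score_individuals(
    model: PrsModel,
    dosages: np.ndarray,
    variants: pd.DataFrame,
    allele_freqs: np.ndarray | None = None,
    impute_missing: bool = True,
    average: bool = True,
) -> pd.DataFrame:
    """Score a cohort with a PRS model (PLINK-default semantics).

    The risk-allele dosage is the coded (ALT) dosage when the model's risk
    allele matches ALT and ``2 - dosage`` when it matches REF.  Missing
    dosages are replaced by ``2 * freq(risk allele)`` when
    ``impute_missing`` (freqs default to the scoring cohort's own);
    ``average`` divides by twice the per-individual count of scored SNPs.
    Model SNPs absent from the cohort are dropped with a logged count.
    Returns a DataFrame with ``prs``, ``prs_std`` (cohort-standardized) and
    ``n_snps_used``.
    """
    if model.is_empty:
        raise ValueError("cannot score with an empty PRS model")
    col_of = {sid: j for j, sid in enumerate(variants["snp_id"])}
    alt = variants["alt"].to_numpy()
    ref = variants["ref"].to_numpy()
    if allele_freqs is None:
        with np.errstate(invalid="ignore"):
            allele_freqs = np.nanmean(dosages, axis=0) / 2.0
    n = dosages.shape[0]
    num = np.zeros(n)
    m_used = np.zeros(n)
    n_missing_model = 0
    for row in model.snps.itertuples():
        j = col_of.get(row.snp_id)
        if j is None:
            n_missing_model += 1
            continue
        d = dosages[:, j]
        if row.risk_allele == alt[j]:
            d_risk, f_risk = d, allele_freqs[j]
        elif row.risk_allele == ref[j]:
            d_risk, f_risk = 2.0 - d, 1.0 - allele_freqs[j]
        else:
            logger.warning(
                "score_individuals: allele mismatch for %s; SNP skipped", row.snp_id
            )
            n_missing_model += 1
            continue
        miss = np.isnan(d_risk)
        if impute_missing:
            d_risk = np.where(miss, 2.0 * f_risk, d_risk)
            num += row.weight * d_risk
            m_used += 1.0
        else:
            num += row.weight * np.where(miss, 0.0, d_risk)
            m_used += (~miss).astype(float)
    if n_missing_model:
        logger.info(
            "score_individuals: %d model SNP(s) absent from cohort", n_missing_model
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        prs = num / (2.0 * m_used) if average else num
    prs = np.where(m_used > 0, prs, np.nan)
    sd = np.nanstd(prs)
    prs_std = (prs - np.nanmean(prs)) / sd if sd > 0 else np.zeros_like(prs)
    return pd.DataFrame(
        {"prs": prs, "prs_std": prs_std, "n_snps_used": m_used.astype(np.int64)}
    )


def scan_thresholds(
    models: dict[float, PrsModel],
    dosages: np.ndarray,
    variants: pd.DataFrame,
    trait_values,
    covariates: pd.DataFrame,
    allele_freqs: np.ndarray | None = None,
    impute_missing: bool = True,
) -> tuple[pd.DataFrame, float]:
    """Incremental-R^2 threshold scan on a validation cohort.

    Evaluates every model of the fixed grid (empty models score an
    incremental R^2 of 0, keeping the scan complete) and returns the scan
    table plus the selected threshold — the argmax of incremental R^2, with
    ties broken toward the smaller threshold.
    """
    grid = sorted(models)
    if set(grid) != set(THRESHOLD_GRID):
        raise ValueError("scan requires exactly the seven grid thresholds")
    if all(m.is_empty for m in models.values()):
        raise ValueError("all PRS models are empty; nothing to scan")
    rows = []
    for thr in grid:
        model = models[thr]
        if model.is_empty:
            rows.append((thr, 0, 0.0, np.nan))
            continue
        scores = score_individuals(
            model, dosages, variants, allele_freqs, impute_missing=impute_missing
        )
        fit = _evaluate.incremental_r2(trait_values, scores["prs"], covariates)
        rows.append((thr, model.n_snps, fit.r2_increment, fit.prs_p))
    scan = pd.DataFrame(rows, columns=["threshold", "n_snps", "r2_increment", "prs_p"])
    best = scan.loc[scan["r2_increment"].idxmax()]  # idxmax -> first (smallest thr)
    return scan, float(best["threshold"])


def model_to_frames(model: PrsModel) -> tuple[pd.DataFrame, dict]:
    """TSV table + JSON sidecar describing a model."""
    sidecar = {
        "trait": model.trait,
        "pathway_id": model.pathway_id,
        "threshold": model.threshold,
        "n_snps": model.n_snps,
        "n_genes": model.n_genes,
    }
    return model.snps.copy(), sidecar
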