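"""End-to-end three-cohort workflow: QC -> PCs -> GWAS -> clump -> C+T -> evaluation.

The discovery cohort provides per-SNP effect sizes, the validation cohort
serves both as the LD reference panel for clumping (ancestry-matched to the
evaluation cohorts) and as the threshold-selection set, and the target
cohort is held out for final evaluation.  Every per-trait, per-pathway model
is carried through the full seven-threshold scan; evaluation reports
incremental R^2, the decile 1 vs 10 contrast, hypertension AUC, and the
pairwise correlation of pathway PRSs in the discovery cohort.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import assoc as assoc_mod
from . import evaluate as eval_mod
from . import score as score_mod
from .exceptions import PipelineStageError
from .ldclump import ClumpedSet, LdParams, greedy_clump
from .pathways import COMBINED, PathwaySet, map_snps
from .score import THRESHOLD_GRID, PrsModel
from .synthdata import SyntheticCohort

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class QcParams:
    maf_min: float = 0.05
    miss_max: float = 0.05
    hwe_alpha: float = 1e-6


@dataclass
class CohortState:
    """A cohort after QC and phenotype/covariate preparation."""

    name: str
    dosages: np.ndarray
    variants: pd.DataFrame
    phenotypes: pd.DataFrame  # includes *_adj traits and htn
    covariates: pd.DataFrame  # age, sex, pc1..pck
    allele_freqs: np.ndarray


@dataclass
class TraitPathwayResult:
    trait: str
    pathway_id: str
    scan: pd.DataFrame
    threshold: float
    model: PrsModel
    fit: eval_mod.IncrementalFit | None
    deciles: eval_mod.DecileReport | None
    discrimination: dict[str, eval_mod.DiscriminationReport] = field(
        default_factory=dict
    )


@dataclass
class PipelineResult:
    assoc: dict[str, pd.DataFrame]
    clumped: dict[str, ClumpedSet]
    snp_map: dict[str, np.ndarray]
    results: dict[tuple[str, str], TraitPathwayResult]
    correlations: dict[str, pd.DataFrame]
    summary: pd.DataFrame


def prepare_cohort(
    cohort: SyntheticCohort, qc: QcParams = QcParams(), n_pcs: int = 5
) -> CohortState:
    """QC the genotypes, derive adjusted traits, and compute PC covariates."""
    try:
        variants, dosages, _log = assoc_mod.qc_filter(
            cohort.variants, cohort.genotypes,
            maf_min=qc.maf_min, miss_max=qc.miss_max, hwe_alpha=qc.hwe_alpha,
        )
        phen = assoc_mod.prepare_phenotypes(cohort.phenotypes)
        k = min(n_pcs, dosages.shape[0] - 1)
        pcs = assoc_mod.compute_pcs(dosages, k=k, variants=variants)
        cov = assoc_mod.covariate_matrix(phen, pcs)
    except Exception as exc:
        raise PipelineStageError(
            f"prepare_cohort failed for cohort {cohort.name!r}: {exc}"
        ) from exc
    with np.errstate(invalid="ignore"):
        freqs = np.nanmean(dosages, axis=0) / 2.0
    return CohortState(
        name=cohort.name, dosages=dosages, variants=variants,
        phenotypes=phen, covariates=cov, allele_freqs=freqs,
    )


def run_end_to_end(
    cohorts: Mapping[str, SyntheticCohort],
    pathway_set: PathwaySet,
    traits: Sequence[str] = assoc_mod.TRAITS,
    qc: QcParams = QcParams(),
    ld: LdParams = LdParams(),
    n_pcs: int = 5,
    flank_bp: int = 0,
    welch: bool = False,
    impute_missing: bool = True,
) -> PipelineResult:
    """Run the full discovery -> validation -> target workflow in memory.

    ``cohorts`` must map the three roles (discovery, validation, target) to
    cohort data; ``ld.ref_cohort`` names which of them anchors the LD r^2
    estimates (the validation cohort by default).
    """
    for role in ("discovery", "validation", "target"):
        if role not in cohorts:
            raise PipelineStageError(f"missing cohort role {role!r}")
    if ld.ref_cohort not in cohorts:
        raise PipelineStageError(f"unknown LD reference cohort {ld.ref_cohort!r}")

    states = {role: prepare_cohort(c, qc=qc, n_pcs=n_pcs) for role, c in cohorts.items()}
    disc, valid, target = states["discovery"], states["validation"], states["target"]
    ref = states[ld.ref_cohort]

    snp_map = map_snps(disc.variants, pathway_set, flank_bp=flank_bp)
    pathway_ids = [*pathway_set.pathway_ids, COMBINED]

    assoc_by_trait: dict[str, pd.DataFrame] = {}
    clumped_by_trait: dict[str, ClumpedSet] = {}
    results: dict[tuple[str, str], TraitPathwayResult] = {}
    r2_cache: dict = {}
    disc_scores_for_corr: dict[str, dict[str, pd.Series]] = {t: {} for t in traits}
    summary_rows = []

    for trait in traits:
        col = assoc_mod.trait_column(trait)
        try:
            assoc = assoc_mod.gwas_additive(
                disc.dosages, disc.phenotypes[col], disc.covariates, disc.variants
            )
        except Exception as exc:
            raise PipelineStageError(f"gwas failed for trait {trait!r}: {exc}") from exc
        assoc_by_trait[trait] = assoc
        try:
            clumped = greedy_clump(
                assoc, ref.dosages, ref.variants, params=ld, r2_cache=r2_cache
            )
        except Exception as exc:
            raise PipelineStageError(f"clump failed for trait {trait!r}: {exc}") from exc
        clumped_by_trait[trait] = clumped

        for pid in pathway_ids:
            models = {
                thr: score_mod.build_model(
                    assoc, clumped, snp_map, disc.variants, trait, pid, thr,
                    pathway_set=pathway_set,
                )
                for thr in THRESHOLD_GRID
            }
            if all(m.is_empty for m in models.values()):
                logger.warning(
                    "pipeline: all models empty for trait=%s pathway=%s", trait, pid
                )
                results[(trait, pid)] = TraitPathwayResult(
                    trait=trait, pathway_id=pid,
                    scan=pd.DataFrame(
                        {"threshold": THRESHOLD_GRID, "n_snps": 0,
                         "r2_increment": 0.0, "prs_p": np.nan}
                    ),
                    threshold=min(THRESHOLD_GRID),
                    model=models[min(THRESHOLD_GRID)], fit=None, deciles=None,
                )
                continue
            scan, selected = score_mod.scan_thresholds(
                models, valid.dosages, valid.variants,
                valid.phenotypes[col], valid.covariates,
                allele_freqs=valid.allele_freqs, impute_missing=impute_missing,
            )
            model = models[selected]
            tp = TraitPathwayResult(
                trait=trait, pathway_id=pid, scan=scan,
                threshold=selected, model=model, fit=None, deciles=None,
            )
            if not model.is_empty:
                target_scores = score_mod.score_individuals(
                    model, target.dosages, target.variants,
                    allele_freqs=target.allele_freqs, impute_missing=impute_missing,
                )
                tp.fit = eval_mod.incremental_r2(
                    target.phenotypes[col], target_scores["prs"], target.covariates
                )
                tp.deciles = eval_mod.decile_contrast(
                    target_scores["prs"].to_numpy(),
                    target.phenotypes[col].to_numpy(),
                    welch=welch,
                )
                tp.discrimination["htn"] = eval_mod.auc_mann_whitney(
                    target_scores["prs"], target.phenotypes["htn"]
                )
                disc_scores = score_mod.score_individuals(
                    model, disc.dosages, disc.variants,
                    allele_freqs=disc.allele_freqs, impute_missing=impute_missing,
                )
                disc_scores_for_corr[trait][pid] = disc_scores["prs"]
            results[(trait, pid)] = tp
            summary_rows.append(_summary_row(tp))

    correlations = {}
    for trait in traits:
        cols = disc_scores_for_corr[trait]
        if len(cols) >= 2:
            correlations[trait] = eval_mod.prs_correlation_matrix(pd.DataFrame(cols))

    summary = pd.DataFrame(summary_rows)
    return PipelineResult(
        assoc=assoc_by_trait, clumped=clumped_by_trait, snp_map=snp_map,
        results=results, correlations=correlations, summary=summary,
    )


def _summary_row(tp: TraitPathwayResult) -> dict:
    row = {
        "trait": tp.trait,
        "pathway_id": tp.pathway_id,
        "threshold": tp.threshold,
        "n_snps": tp.model.n_snps,
        "n_genes": tp.model.n_genes,
    }
    if tp.fit is not None:
        row.update(
            r2_base=tp.fit.r2_base, r2_full=tp.fit.r2_full,
            r2_increment=tp.fit.r2_increment, pct_increase=tp.fit.pct_increase,
            prs_beta=tp.fit.prs_beta, prs_p=tp.fit.prs_p,
        )
    if tp.deciles is not None:
        row.update(
            decile_t=tp.deciles.t, decile_df=tp.deciles.df,
            decile_p=tp.deciles.p, cohens_d=tp.deciles.cohens_d,
            decile1_mean=float(tp.deciles.table["mean"].iloc[0]),
            decile10_mean=float(tp.deciles.table["mean"].iloc[-1]),
        )
    if "htn" in tp.discrimination:
        disc = tp.discrimination["htn"]
        row.update(auc=disc.auc, auc_ci_low=disc.ci_low, auc_ci_high=disc.ci_high)
    return row
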