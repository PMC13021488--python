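"""Synthetic three-cohort generator for blood-pressure PRS pipelines.

The generator emulates the statistical structure the pipeline assumes about
its (restricted) input cohorts: LD-blocked genotypes with minor allele
frequency >= 0.05, additive polygenic effects on systolic/diastolic blood
pressure optionally concentrated inside designated pathways, age and sex
covariate effects, latent population-structure axes, and an
antihypertensive-medication indicator that is more likely at high latent
blood pressure (treated readings are lowered by a fixed 15/10 mmHg, so the
standard +15/+10 medication adjustment is exactly correct here).

Genotypes are produced by thresholding correlated Gaussian haplotypes: each
individual carries two haplotypes; within an LD block the per-SNP latent
Gaussians share a haplotype-level factor with loading ``sqrt(block_rho)``,
giving tunable within-block r^2 and near-zero r^2 across blocks.  Blocks sit
on a single synthetic chromosome with >300 kb gaps so a 250 kb clumping
window cleanly separates them.

Reproducibility: all draws descend from ``SimConfig.seed`` through fixed
child streams — locus-level parameters (positions, allele frequencies,
structure loadings, true effects) are shared by the three cohorts, while
haplotype and phenotype noise use disjoint per-cohort streams.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from . import io as io_
from .exceptions import ConfigError
from .pathways import (
    ANTIHYPERTENSIVE_PATHWAYS,
    GeneInterval,
    PathwaySet,
    map_snps,
)

logger = logging.getLogger(__name__)

COHORTS = ("discovery", "validation", "target")

# child-stream tags appended to the master seed
_STREAM_LOCI = 7
_STREAM_EFFECTS = 11
_STREAM_ANNOT = 13
_STREAM_GENO = {"discovery": 21, "validation": 22, "target": 23}
_STREAM_PHENO = {"discovery": 31, "validation": 32, "target": 33}


@dataclass(frozen=True)
class SimConfig:
    """Study-condition parameters for the synthetic cohorts.

    Defaults mirror the study the pipeline is built for: cohort sizes
    2,295 / 1,614 / 966 (discovery / validation / target), blood-pressure
    means and SDs near 160/29.5 (SBP) and 101/18.2 (DBP) mmHg in the
    discovery cohort with lower means in validation and target, age ~49 +/-
    11 years, and a medication-use prevalence rising with latent pressure.
    """

    n_discovery: int = 2295
    n_validation: int = 1614
    n_target: int = 966
    n_blocks: int = 60
    snps_per_block: int = 20
    maf_range: tuple[float, float] = (0.05, 0.5)
    block_rho: float = 0.8
    causal_pathways: tuple[str, ...] = ()
    causal_snps_per_gene: int = 2
    h2_per_trait: Mapping[str, float] = field(
        default_factory=lambda: {"sbp": 0.15, "dbp": 0.15}
    )
    beta_age: float = 0.5  # mmHg per year on SBP (half on DBP)
    beta_sex: float = 3.0  # mmHg added for sex == 1 (male)
    n_structure_axes: int = 2
    struct_var_frac: float = 0.02  # trait-variance share per structure axis
    med_logit_slope: float = 1.5  # per SD of latent SBP
    med_intercept: float = -2.0
    treatment_effect: tuple[float, float] = (15.0, 10.0)  # SBP, DBP lowering
    female_frac: float = 0.5
    trait_mean: Mapping[str, float] = field(
        default_factory=lambda: {"sbp": 159.7, "dbp": 101.3}
    )
    trait_sd: Mapping[str, float] = field(
        default_factory=lambda: {"sbp": 29.5, "dbp": 18.2}
    )
    age_mean: float = 48.7
    age_sd: float = 11.2
    #: per-cohort additive shift of (SBP, DBP) means, emulating the observed
    #: cohort-level differences (validation ~20 mmHg lower).
    cohort_mean_shift: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "validation": (-24.3, -17.6),
            "target": (-7.7, -7.7),
        }
    )
    beta_cor: float = 0.6  # correlation of SBP and DBP causal effects
    noise_cor: float = 0.5  # correlation of SBP and DBP residual noise
    pathway_ids: tuple[str, ...] = tuple(ANTIHYPERTENSIVE_PATHWAYS)
    overlap_prob: float = 0.15  # chance a gene joins a second pathway
    seed: int = 2026

    # -- validation ---------------------------------------------------------
    def validate(self) -> None:
        for name in ("n_discovery", "n_validation", "n_target"):
            if getattr(self, name) < 2:
                raise ConfigError(f"{name} must be >= 2")
        if self.n_blocks < 1:
            raise ConfigError("n_blocks must be >= 1")
        if self.snps_per_block < 1:
            raise ConfigError("snps_per_block must be >= 1")
        lo, hi = self.maf_range
        if not (0.05 <= lo <= hi <= 0.5):
            raise ConfigError("maf_range must satisfy 0.05 <= lo <= hi <= 0.5")
        if not (0.0 <= self.block_rho < 1.0):
            raise ConfigError("block_rho must be in [0, 1)")
        for trait, h2 in self.h2_per_trait.items():
            if not (0.0 <= h2 < 1.0):
                raise ConfigError(f"h2_per_trait[{trait}] must be in [0, 1)")
        if self.n_structure_axes < 0:
            raise ConfigError("n_structure_axes must be >= 0")
        if self.causal_snps_per_gene < 1:
            raise ConfigError("causal_snps_per_gene must be >= 1")
        unknown = set(self.causal_pathways) - set(self.pathway_ids)
        if unknown:
            raise ConfigError(f"causal_pathways not in pathway_ids: {sorted(unknown)}")
        if not (0.0 <= self.female_frac <= 1.0):
            raise ConfigError("female_frac must be in [0, 1]")

    @property
    def n_snps(self) -> int:
        return self.n_blocks * self.snps_per_block

    def cohort_size(self, cohort: str) -> int:
        return {
            "discovery": self.n_discovery,
            "validation": self.n_validation,
            "target": self.n_target,
        }[cohort]


@dataclass
class SyntheticCohort:
    """One simulated cohort plus its generative ground truth."""

    name: str
    genotypes: np.ndarray  # individuals x SNPs dosages in [0, 2]
    variants: pd.DataFrame  # snp_id, chrom, pos, ref, alt, maf
    phenotypes: pd.DataFrame  # sample_id, sbp, dbp, age, sex, med_use
    truth: dict

    @property
    def n(self) -> int:
        return self.genotypes.shape[0]


# ---------------------------------------------------------------------------
# locus-level parameters (shared by all cohorts)
# ---------------------------------------------------------------------------

def _block_layout(config: SimConfig) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Positions, block index and block start for every SNP.

    Within-block span <= 250 kb (all same-block pairs fall inside the
    clumping window); consecutive blocks are separated by > 300 kb.
    """
    s = config.snps_per_block
    spacing = max(1, 250_000 // max(s, 1)) if s > 1 else 1
    span = spacing * (s - 1)
    starts = 1 + np.arange(config.n_blocks, dtype=np.int64) * (span + 300_001)
    pos = (starts[:, None] + np.arange(s, dtype=np.int64)[None, :] * spacing).ravel()
    block = np.repeat(np.arange(config.n_blocks), s)
    return pos, block, starts


def _locus_params(config: SimConfig) -> pd.DataFrame:
    """Deterministic per-SNP parameters: position, target allele frequency."""
    rng = np.random.default_rng([config.seed, _STREAM_LOCI])
    pos, block, _ = _block_layout(config)
    m = config.n_snps
    lo, hi = config.maf_range
    p = rng.uniform(lo, hi, size=m)
    alleles = np.array([("A", "G"), ("C", "T"), ("G", "A"), ("T", "C")])
    pick = rng.integers(0, len(alleles), size=m)
    return pd.DataFrame(
        {
            "snp_id": [f"rs{100000 + i}" for i in range(m)],
            "chrom": "1",
            "pos": pos,
            "ref": alleles[pick, 0],
            "alt": alleles[pick, 1],
            "block": block,
            "p_alt": p,
        }
    )


def _structure_loadings(config: SimConfig) -> np.ndarray:
    """Per-SNP latent-mean shifts per structure axis (shared across cohorts)."""
    rng = np.random.default_rng([config.seed, _STREAM_LOCI, 2])
    return rng.normal(0.0, 0.15, size=(config.n_snps, config.n_structure_axes))


def simulate_annotation(config: SimConfig) -> PathwaySet:
    """Synthetic gene/pathway annotation aligned to the LD-block layout.

    Each LD block is one gene spanning exactly its SNPs; genes are dealt
    round-robin to the configured pathways (so every pathway is non-empty
    when ``n_blocks >= len(pathway_ids)``) and join a second pathway with
    probability ``overlap_prob``.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, _STREAM_ANNOT])
    pos, block, starts = _block_layout(config)
    n_path = len(config.pathway_ids)
    genes = [f"GENE{b:04d}" for b in range(config.n_blocks)]
    intervals: dict[str, list[GeneInterval]] = {}
    for b, g in enumerate(genes):
        sel = pos[block == b]
        intervals[g] = [GeneInterval(g, "1", int(sel.min()), int(sel.max()))]
    order = rng.permutation(config.n_blocks)
    membership: dict[str, set[str]] = {pid: set() for pid in config.pathway_ids}
    for rank, b in enumerate(order):
        primary = config.pathway_ids[rank % n_path]
        membership[primary].add(genes[b])
        if n_path > 1 and rng.random() < config.overlap_prob:
            other = config.pathway_ids[int(rng.integers(0, n_path))]
            if other != primary:
                membership[other].add(genes[b])
    pathway_map = {
        pid: (ANTIHYPERTENSIVE_PATHWAYS.get(pid, pid), frozenset(members))
        for pid, members in membership.items()
    }
    return PathwaySet(pathways=pathway_map, intervals=intervals)


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def simulate_genotypes(
    config: SimConfig, n: int, cohort: str = "discovery"
) -> tuple[np.ndarray, pd.DataFrame, np.ndarray]:
    """Simulate ``n`` individuals' dosages plus the variant table.

    Returns ``(dosages, variants, structure_scores)``.  Realized MAF is
    guaranteed >= 0.05 by per-SNP rejection (fresh idiosyncratic noise) with
    a rank-based assignment fallback that pins the allele count exactly.
    """
    config.validate()
    if n < 2:
        raise ConfigError("n must be >= 2")
    loci = _locus_params(config)
    loadings = _structure_loadings(config)
    rng = np.random.default_rng(
        [config.seed, _STREAM_GENO.get(cohort, abs(hash(cohort)) % 2**31)]
    )
    u = rng.standard_normal((n, config.n_structure_axes))
    rho = config.block_rho
    m = config.n_snps
    dosages = np.empty((n, m), dtype=np.float64)
    min_count = int(np.ceil(0.05 * 2 * n))
    for b in range(config.n_blocks):
        cols = np.flatnonzero(loci["block"].to_numpy() == b)
        s = cols.size
        p = loci["p_alt"].to_numpy()[cols]
        shift = u @ loadings[cols].T  # (n, s)
        f = rng.standard_normal((n, 2))  # shared haplotype factor
        thr = stats.norm.ppf(p)

        def draw(column_subset: np.ndarray) -> np.ndarray:
            eps = rng.standard_normal((n, 2, column_subset.size))
            z = (
                np.sqrt(rho) * f[:, :, None]
                + np.sqrt(1.0 - rho) * eps
                + shift[:, None, :][:, :, column_subset]
            )
            return (z < thr[column_subset]).sum(axis=1).astype(np.float64), z

        active = np.arange(s)
        d_block = np.empty((n, s))
        z_last = np.empty((n, 2, s))
        for _try in range(20):
            d_new, z_new = draw(active)
            d_block[:, active] = d_new
            z_last[:, :, active] = z_new
            freq = d_block[:, active].mean(axis=0) / 2.0
            maf = np.minimum(freq, 1.0 - freq)
            active = active[maf < 0.05]
            if active.size == 0:
                break
        for j in active:  # rank-based fallback: pin allele count exactly
            z = z_last[:, :, j].ravel()
            k = int(np.clip(round(2 * n * p[j]), min_count, 2 * n - min_count))
            hap = np.zeros(2 * n)
            hap[np.argsort(z, kind="stable")[:k]] = 1.0
            d_block[:, j] = hap.reshape(n, 2).sum(axis=1)
        dosages[:, cols] = d_block
    freq = dosages.mean(axis=0) / 2.0
    variants = loci.drop(columns=["p_alt"]).copy()
    variants["maf"] = np.minimum(freq, 1.0 - freq)
    return dosages, variants, u


# ---------------------------------------------------------------------------
# true effects (shared across cohorts)
# ---------------------------------------------------------------------------

def _expected_dosage_cov(config: SimConfig, loci: pd.DataFrame, idx: np.ndarray) -> np.ndarray:
    """Expected covariance matrix of causal-SNP dosages under the haplotype model.

    Same-block latent Gaussians have correlation ``block_rho``; the allele
    covariance is the bivariate-normal orthant probability minus the product
    of marginals, and dosages carry two independent haplotypes.
    """
    p = loci["p_alt"].to_numpy()[idx]
    block = loci["block"].to_numpy()[idx]
    thr = stats.norm.ppf(p)
    k = idx.size
    cov = np.diag(2.0 * p * (1.0 - p))
    rho = config.block_rho
    if rho > 0:
        for i in range(k):
            for j in range(i + 1, k):
                if block[i] != block[j]:
                    continue
                joint = stats.multivariate_normal.cdf(
                    [thr[i], thr[j]], mean=[0.0, 0.0], cov=[[1.0, rho], [rho, 1.0]]
                )
                cov[i, j] = cov[j, i] = 2.0 * (joint - p[i] * p[j])
    return cov


def true_effects(config: SimConfig, pathways: PathwaySet) -> pd.DataFrame:
    """Draw per-SNP true effects for SBP and DBP (population parameters).

    Effects are nonzero only at causal SNPs: ``causal_snps_per_gene`` SNPs
    sampled per gene of the causal pathways (all genes when
    ``causal_pathways`` is empty), scaled so the expected genetic variance
    equals ``h2 * trait_sd^2``.  SBP and DBP effects share correlation
    ``beta_cor``.
    """
    config.validate()
    loci = _locus_params(config)
    variants = loci.drop(columns=["p_alt"])
    rng = np.random.default_rng([config.seed, _STREAM_EFFECTS])
    snp_map = map_snps(variants, pathways)
    if config.causal_pathways:
        genes: set[str] = set()
        for pid in config.causal_pathways:
            genes |= set(pathways.genes(pid))
    else:
        genes = set(pathways.intervals)
    eligible_by_gene = {}
    pos = loci["pos"].to_numpy()
    for g in sorted(genes):
        for iv in pathways.intervals_for(g):
            mask = (pos >= iv.start) & (pos <= iv.end)
            eligible_by_gene[g] = np.flatnonzero(mask)
    causal: list[int] = []
    for g in sorted(eligible_by_gene):
        cand = eligible_by_gene[g]
        if cand.size == 0:
            continue
        k = min(config.causal_snps_per_gene, cand.size)
        causal.extend(rng.choice(cand, size=k, replace=False).tolist())
    causal_idx = np.array(sorted(set(causal)), dtype=np.intp)
    m = config.n_snps
    betas = pd.DataFrame(
        {"snp_id": loci["snp_id"], "sbp": np.zeros(m), "dbp": np.zeros(m)}
    )
    if causal_idx.size == 0:
        return betas
    rc = config.beta_cor
    raw_s = rng.standard_normal(causal_idx.size)
    raw_d = rc * raw_s + np.sqrt(1 - rc**2) * rng.standard_normal(causal_idx.size)
    cov = _expected_dosage_cov(config, loci, causal_idx)
    for trait, raw in (("sbp", raw_s), ("dbp", raw_d)):
        h2 = config.h2_per_trait.get(trait, 0.0)
        if h2 <= 0:
            continue
        sigma2 = config.trait_sd[trait] ** 2
        var_raw = float(raw @ cov @ raw)
        scale = np.sqrt(h2 * sigma2 / var_raw)
        betas.loc[causal_idx, trait] = raw * scale
    return betas


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------

def simulate_phenotypes(
    genotypes: np.ndarray,
    variants: pd.DataFrame,
    pathways: PathwaySet,
    config: SimConfig,
    cohort: str = "discovery",
    structure_scores: np.ndarray | None = None,
    betas: pd.DataFrame | None = None,
) -> SyntheticCohort:
    """Generate phenotypes on top of a simulated genotype matrix.

    Latent (pre-treatment) SBP/DBP = mean + genetic score + age and sex
    effects + structure-axis effects + Gaussian noise; medication use is
    Bernoulli with a logistic probability in standardized latent SBP, and
    treated individuals' observed readings are lowered by the configured
    treatment effect (default 15/10 mmHg).
    """
    config.validate()
    n = genotypes.shape[0]
    if genotypes.shape[1] != len(variants):
        raise ConfigError("genotype matrix not aligned to variants")
    if betas is None:
        betas = true_effects(config, pathways)
    if structure_scores is None:
        structure_scores = np.zeros((n, config.n_structure_axes))
    rng = np.random.default_rng(
        [config.seed, _STREAM_PHENO.get(cohort, abs(hash(cohort)) % 2**31)]
    )

    age = np.clip(rng.normal(config.age_mean, config.age_sd, size=n), 18.0, 95.0)
    sex = (rng.random(n) >= config.female_frac).astype(np.int64)  # 1 = male
    freq = genotypes.mean(axis=0) / 2.0
    centered = genotypes - 2.0 * freq

    shift = dict(config.cohort_mean_shift).get(cohort, (0.0, 0.0))
    noise = {}
    rn = config.noise_cor
    e1 = rng.standard_normal(n)
    e2 = rn * e1 + np.sqrt(1 - rn**2) * rng.standard_normal(n)
    raw_noise = {"sbp": e1, "dbp": e2}
    latent = {}
    genetic = {}
    for ti, trait in enumerate(("sbp", "dbp")):
        sigma2 = config.trait_sd[trait] ** 2
        h2 = config.h2_per_trait.get(trait, 0.0)
        g = centered @ betas[trait].to_numpy()
        beta_age = config.beta_age if trait == "sbp" else 0.5 * config.beta_age
        cov_comp = beta_age * (age - config.age_mean) + config.beta_sex * (
            sex - sex.mean()
        )
        struct_delta = np.sqrt(config.struct_var_frac * sigma2)
        struct_comp = structure_scores.sum(axis=1) * struct_delta
        var_explained = (
            h2 * sigma2
            + float(np.var(cov_comp))
            + config.struct_var_frac * sigma2 * config.n_structure_axes
        )
        var_noise = sigma2 - var_explained
        if var_noise <= 0:
            raise ConfigError(
                f"h2_per_trait[{trait}] infeasible: explained variance "
                f"{var_explained:.1f} exceeds total {sigma2:.1f}"
            )
        mean = config.trait_mean[trait] + shift[ti]
        latent[trait] = (
            mean + g + cov_comp + struct_comp + np.sqrt(var_noise) * raw_noise[trait]
        )
        genetic[trait] = g
        noise[trait] = var_noise

    z = (latent["sbp"] - config.trait_mean["sbp"] - shift[0]) / config.trait_sd["sbp"]
    p_med = expit(config.med_intercept + config.med_logit_slope * z)
    med_use = (rng.random(n) < p_med).astype(np.int64)
    te_sbp, te_dbp = config.treatment_effect
    sbp_obs = latent["sbp"] - te_sbp * med_use
    dbp_obs = latent["dbp"] - te_dbp * med_use

    sample_ids = [f"{cohort}_{i:05d}" for i in range(n)]
    phen = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "sbp": sbp_obs,
            "dbp": dbp_obs,
            "age": age,
            "sex": sex,
            "med_use": med_use,
        }
    )
    truth = {
        "betas": betas,
        "structure_scores": structure_scores,
        "genetic_score": pd.DataFrame(
            {"sample_id": sample_ids, "sbp": genetic["sbp"], "dbp": genetic["dbp"]}
        ),
        "latent": pd.DataFrame(
            {"sample_id": sample_ids, "sbp": latent["sbp"], "dbp": latent["dbp"]}
        ),
    }
    return SyntheticCohort(
        name=cohort, genotypes=genotypes, variants=variants, phenotypes=phen, truth=truth
    )


def simulate_cohort(
    config: SimConfig, cohort: str, pathways: PathwaySet | None = None,
    betas: pd.DataFrame | None = None,
) -> SyntheticCohort:
    if pathways is None:
        pathways = simulate_annotation(config)
    n = config.cohort_size(cohort)
    dosages, variants, u = simulate_genotypes(config, n, cohort=cohort)
    return simulate_phenotypes(
        dosages, variants, pathways, config, cohort=cohort,
        structure_scores=u, betas=betas,
    )


def simulate_cohorts(config: SimConfig) -> tuple[dict[str, SyntheticCohort], PathwaySet]:
    """Generate the three non-overlapping cohorts plus the shared annotation."""
    config.validate()
    pathways = simulate_annotation(config)
    betas = true_effects(config, pathways)
    cohorts = {
        name: simulate_cohort(config, name, pathways=pathways, betas=betas)
        for name in COHORTS
    }
    ids = [set(c.phenotypes["sample_id"]) for c in cohorts.values()]
    assert not (ids[0] & ids[1]) and not (ids[0] & ids[2]) and not (ids[1] & ids[2])
    return cohorts, pathways


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------

def write_cohort(cohort: SyntheticCohort, directory: str | Path) -> dict[str, Path]:
    """Write one cohort to ``directory``: VCF (GT+DS), phenotype and truth TSVs.

    The files round-trip bit-identically through :mod:`pathprs.io` readers.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    sample_ids = cohort.phenotypes["sample_id"].tolist()
    paths = {
        "vcf": directory / f"{cohort.name}.vcf",
        "phenotypes": directory / f"{cohort.name}.phenotypes.tsv",
        "truth_snps": directory / f"{cohort.name}.truth_snps.tsv",
        "truth_samples": directory / f"{cohort.name}.truth_samples.tsv",
    }
    io_.write_vcf(paths["vcf"], cohort.genotypes, cohort.variants, sample_ids)
    cohort.phenotypes.to_csv(paths["phenotypes"], sep="\t", index=False)

    betas = cohort.truth["betas"]
    long = betas.melt(id_vars="snp_id", var_name="trait", value_name="beta_true")
    long.to_csv(paths["truth_snps"], sep="\t", index=False)

    samples = cohort.truth["genetic_score"].rename(
        columns={"sbp": "g_sbp", "dbp": "g_dbp"}
    )
    u = cohort.truth["structure_scores"]
    for k in range(u.shape[1]):
        samples[f"axis{k + 1}"] = u[:, k]
    samples.to_csv(paths["truth_samples"], sep="\t", index=False)
    return paths


def read_cohort(directory: str | Path, name: str) -> SyntheticCohort:
    """Read back a cohort written by :func:`write_cohort` (truth included)."""
    directory = Path(directory)
    dosages, variants, sample_ids = io_.read_vcf(directory / f"{name}.vcf")
    phen = io_.read_phenotypes(directory / f"{name}.phenotypes.tsv")
    if phen["sample_id"].tolist() != sample_ids:
        raise ValueError(f"{name}: sample order differs between VCF and phenotypes")
    long = pd.read_csv(directory / f"{name}.truth_snps.tsv", sep="\t")
    betas = long.pivot(index="snp_id", columns="trait", values="beta_true")
    betas = betas.reindex(variants["snp_id"]).reset_index()
    samples = pd.read_csv(directory / f"{name}.truth_samples.tsv", sep="\t")
    axes = [c for c in samples.columns if c.startswith("axis")]
    truth = {
        "betas": betas,
        "structure_scores": samples[axes].to_numpy(),
        "genetic_score": samples[["sample_id", "g_sbp", "g_dbp"]].rename(
            columns={"g_sbp": "sbp", "g_dbp": "dbp"}
        ),
    }
    return SyntheticCohort(
        name=name, genotypes=dosages, variants=variants, phenotypes=phen, truth=truth
    )


def write_annotation(pathways: PathwaySet, directory: str | Path) -> dict[str, Path]:
    from .pathways import write_gene_intervals, write_gmt

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "gmt": directory / "pathways.gmt",
        "intervals": directory / "gene_intervals.tsv",
    }
    write_gmt(pathways.pathways, paths["gmt"])
    write_gene_intervals(pathways.intervals, paths["intervals"])
    return paths


__all__ = [
    "SimConfig",
    "SyntheticCohort",
    "simulate_annotation",
    "simulate_genotypes",
    "simulate_phenotypes",
    "simulate_cohort",
    "simulate_cohorts",
    "true_effects",
    "write_cohort",
    "read_cohort",
    "write_annotation",
    "replace",
]
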