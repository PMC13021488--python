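# Methods

## The model

For each blood-pressure trait `y` (SBP, DBP, MAP, PP, in mmHg) the
discovery association model is per-SNP ordinary least squares

    y_adj = α + β·d + γ_age·age + γ_sex·sex + Σ_k δ_k·PC_k + ε

where `d` is the allele dosage in [0, 2], `y_adj` is the
medication-adjusted trait, and PC_1..PC_5 are genetic principal
components. Two-sided p-values use the t reference with
`n − (#covariates + 2)` degrees of freedom. The risk allele is the
trait-increasing allele: when the ALT-dosage coefficient is negative the
orientation is flipped (REF becomes the risk allele, β := |β|), which
leaves the p-value unchanged.

**Medication adjustment.** Treated individuals' readings are raised by
+15 mmHg (SBP) and +10 mmHg (DBP) before any trait derivation or
regression — the standard fixed-increment approximation of untreated
pressure in BP GWAS. MAP and PP are derived *from the adjusted values*
(PP = SBP − DBP, MAP = (SBP + 2·DBP)/3); applying the same adjustment
upstream of both derived traits is the only self-consistent choice.
Hypertension status, by contrast, is a clinical definition on the *raw*
readings: SBP ≥ 140, DBP ≥ 90 (both inclusive), or medication use.

**Clumping.** Pairwise r² between unphased genotypes is
`D²/(p_A q_A p_B q_B)` with haplotype frequencies estimated by EM over the
double-heterozygote phase ambiguity (convergence when the largest
frequency change < 1e-10, cap 1000 iterations; monomorphic pairs return
0). Greedy clumping visits SNPs by ascending p (ties broken by chromosome,
position, SNP id); each unassigned SNP becomes an index and absorbs
unassigned same-chromosome SNPs within 250 kb with r² > 0.1. r² is always
computed in the designated LD reference cohort — the validation cohort by
default, keeping LD estimation ancestry-matched without an external panel.
Fractional dosages are rounded to hard genotypes for the EM (with a
warning); PLINK-style `--clump-kb` distance semantics
(|Δpos| ≤ window) are used, and cross-chromosome pairs are never clumped.
Secondary clump thresholds are not applied at clump time; the p-value
grid is applied afterwards at model building, which reproduces C+T
behaviour for the grid in use.

**Scoring and threshold selection.** A model for (trait, pathway,
threshold) is the intersection of clumped index SNPs, the pathway's SNP
list, and `p ≤ threshold`, weighted by the oriented discovery β. Scores
are PLINK-default averages `Σ w_j d_ij / (2 m_i)` with missing genotypes
mean-imputed from the risk-allele frequency (both behaviours exposed as
flags, since PLINK 1.9/2.0 defaults differ). The seven-point threshold
grid is fixed; empty models score an incremental R² of 0 so the scan stays
complete, and the selected threshold is the argmax of validation
incremental R² with ties broken toward the smaller threshold. Each trait ×
pathway model selects its threshold independently.

**Evaluation.** Incremental R² is `R²_full − R²_base` from nested OLS
(base: covariates only), reported also as a percent of the base R²
(`pct_increase = 100·ΔR²/R²_base`, undefined when the base R² is 0).
Decile stratification ranks individuals by PRS into ten groups whose sizes
differ by at most one (remainder to the upper deciles, stable tie-break);
the decile 1 vs 10 contrast is a pooled-variance two-sample t with
df = n₁ + n₂ − 2, signed as mean(d1) − mean(d10) (negative when the top
decile is higher), with Welch available as an option. Cohen's d is
reported through the pooled-t identity d = 2|t|/√df, which equals the
classical pooled d for equal group sizes and is the convention consistent
with published decile tables at these sizes. AUC is the Mann–Whitney rank
statistic (half credit for ties); its 95% CI uses the DeLong placement
variance (the CI method is a package choice; analytic and fast at these
n). Pathway-PRS correlations are pairwise-complete Pearson; zero-variance
vectors yield flagged NaN rows.

**SNP → pathway mapping.** Gene intervals are 1-based inclusive (the
convention of GRCh37 gene annotation tables; 0-based half-open input is
converted on read when declared in the file header). A SNP belongs to a
pathway iff its position lies within `[start − flank, end + flank]` of any
member gene on the same chromosome; the default flank is 0 (gene body
only) and is exposed as a parameter since annotations differ on flanking
windows. Gene symbols match case-insensitively after trimming; symbols
without intervals are logged and skipped, never fatal. Chromosome labels
are normalized (`chr1` ≡ `1`); mapping fails only when variants and
intervals share no chromosome at all. The union of all pathways forms the
pseudo-pathway `combined`.

## The synthetic cohorts

The generator emulates the statistical structure the pipeline needs from
its (restricted) input data; it is not a population-genetics simulator.

*Genotypes.* Each individual carries two haplotypes. Within an LD block
the per-SNP latent Gaussians share a haplotype-level factor with loading
√ρ (ρ = `block_rho`, default 0.8), and alleles arise by thresholding at
the quantile of the target allele frequency (drawn uniformly from
`maf_range`, default (0.05, 0.5]). This gives tunable within-block r²
that increases with ρ and near-zero r² across blocks — adequate for
exercising clumping — without attempting realistic human LD maps.
Realized MAF ≥ 0.05 is enforced by redrawing a SNP's idiosyncratic noise
(up to 20 times) and, as a last resort, rank-based allele assignment that
pins the allele count exactly. Blocks sit on one synthetic chromosome,
each spanning ≤ 250 kb with > 300 kb gaps, so the 250 kb clumping window
cleanly separates blocks. Default 60 blocks × 20 SNPs = 1,200 SNPs.

*Annotation.* One gene per block, genes dealt round-robin to the eleven
pathway ids (every pathway non-empty when blocks ≥ pathways) with a 15%
chance of joining a second pathway — producing the overlapping-membership
structure that makes pathway-PRS correlations non-trivial. A static GMT
fixture with the same eleven ids and synthetic membership ships with the
package for parser tests; real KEGG membership retrieval is the user's
responsibility.

*Phenotypes.* Latent (pre-treatment) SBP/DBP = mean + genetic score +
age/sex effects + structure-axis effects + Gaussian noise. True effects
are nonzero only at causal SNPs (2 per gene of the causal pathways by
default; all genes when no causal pathway is named), drawn once as
population parameters shared by all three cohorts and scaled so the
*expected* genetic variance — computed from the haplotype model's dosage
covariance, including within-block LD cross-terms via bivariate-normal
orthant probabilities — equals h²·σ². SBP and DBP effects correlate at
0.6 and their residual noise at 0.5. Defaults: h² = 0.15 per trait;
discovery means/SDs 159.7/29.5 (SBP) and 101.3/18.2 (DBP) mmHg with
per-cohort mean shifts matching the observed cohort differences
(validation ≈ 20 mmHg lower); age 48.7 ± 11.2 years at +0.5 mmHg/yr on
SBP (half on DBP); sex Bernoulli(0.5) at +3 mmHg; two structure axes at
2% of trait variance each (axes shift the latent Gaussians through shared
per-SNP loadings, so genotype PCs can recover them). Medication use is
Bernoulli with logistic probability in standardized latent SBP (slope
1.5/SD, intercept −2, ≈ 18–19% prevalence), and treated readings are
lowered by exactly 15/10 mmHg — so the pipeline's +15/+10 adjustment
recovers latent pressure exactly, making adjustment errors detectable.

*Reproducibility.* All draws descend from one master seed through fixed
child streams: locus parameters, structure loadings, annotation and true
effects are config-level (shared across cohorts); haplotype and phenotype
noise use disjoint per-cohort streams. Identical configs give
bit-identical cohorts; the three cohorts share no sample identifiers.

*What passing tests do not show.* The generator has no admixture,
imputation error, genotyping-array artefacts, realistic LD decay,
gene–environment interplay, or cohort-specific measurement protocols.
Pipeline correctness and calibration results on these cohorts therefore
validate the *method implementation*, not its expected predictive
performance on real African-ancestry cohorts, where incremental R² for BP
traits is typically far below the concentrated-signal synthetic setting.

## Numerical choices and degenerate inputs

- QC: MAF < 0.05 excluded (exactly 0.05 kept), missingness > 0.05
  excluded, HWE exact test (Wigginton-style recurrence on hard genotypes)
  at α = 1e-6; removing every SNP is an error, not a silent empty set.
- PCs: column-standardized SVD after greedy LD pruning (r² < 0.2 within
  250 kb) to stop axes locking onto single LD blocks; deterministic sign
  (largest-magnitude score positive); scores scaled to unit variance.
- GWAS: covariate residualization once per trait
  (Frisch–Waugh–Lovell) for the no-missing fast path; per-SNP
  complete-case least squares when dosages are missing; zero-variance
  SNPs skipped with a log entry; collinear covariates are an error.
- Scoring: individuals with zero usable SNPs get a missing score; empty
  models cannot be scored (error) but participate in scans as ΔR² = 0.
- Decile ties in the PRS are broken by stable input order; pct_increase
  is flagged NaN when the base model explains nothing.

## Problem sizes

The test suite and the acceptance script use scaled problem sizes chosen
to exercise every code path with comfortable statistical power: unit
tests run cohorts of 200–2,000 individuals with 100–300 SNPs; the
end-to-end recovery check uses 800/600/400 individuals × 1,200 SNPs over
10 replicates; the acceptance script's headline run uses the full
2,295/1,614/966 design with 1,200 SNPs. Larger SNP panels change runtime,
not behaviour, since every stage is linear or near-linear in SNP count.

## Known limitations

- Binary-trait (logistic) GWAS, mixed models, relatedness adjustment and
  dominance codings are out of scope; shrinkage weighting methods
  (LDpred2, PRS-CS, lassosum) are deliberately not implemented — C+T is
  the method under study.
- Clumping on external summary-statistic LD matrices and stepwise
  conditional analysis are not supported; the LD reference must be an
  individual-level cohort.
- The EM r² is defined on hard genotypes; dosage uncertainty from
  imputation is ignored beyond rounding (with a warning).
- Whether validation-cohort regressions should use their own PCs or PCs
  projected from discovery is genuinely open; per-cohort PCs were chosen
  for simplicity and are computed identically in every cohort.
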