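"""Target-cohort evaluation of PRS models.

Covers the four headline analyses: incremental variance explained
(R^2 of covariates + PRS minus covariates only, both as an absolute
increment and as a percent of the base R^2), decile stratification with a
two-sample t-test and Cohen's d between the bottom and top PRS deciles,
hypertension discrimination (Mann-Whitney AUC with a DeLong 95% CI), and
pairwise Pearson correlation of pathway PRSs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# incremental R^2
# ---------------------------------------------------------------------------

@dataclass
class IncrementalFit:
    r2_base: float
    r2_full: float
    r2_increment: float
    pct_increase: float  # 100 * increment / base; NaN when base R^2 is 0
    prs_beta: float
    prs_se: float
    prs_p: float
    n: int


def incremental_r2(trait_values, prs, covariates: pd.DataFrame) -> IncrementalFit:
    """R^2 gain from adding the PRS to a covariate-only OLS model.

    Complete cases only; the PRS coefficient, SE and two-sided p come from
    the full model.  A constant PRS yields increment 0 with a warning.
    """
    y = np.asarray(trait_values, dtype=np.float64)
    x = np.asarray(prs, dtype=np.float64)
    C = covariates.to_numpy(dtype=np.float64)
    keep = ~(np.isnan(y) | np.isnan(x) | np.isnan(C).any(axis=1))
    y, x, C = y[keep], x[keep], C[keep]
    n = y.size
    base = sm.OLS(y, sm.add_constant(C)).fit()
    if x.std() == 0:
        logger.warning("incremental_r2: constant PRS; increment is 0")
        return IncrementalFit(
            r2_base=base.rsquared, r2_full=base.rsquared, r2_increment=0.0,
            pct_increase=0.0 if base.rsquared > 0 else np.nan,
            prs_beta=0.0, prs_se=np.nan, prs_p=np.nan, n=n,
        )
    X_full = sm.add_constant(np.column_stack([C, x]))
    full = sm.OLS(y, X_full).fit()
    r2b, r2f = float(base.rsquared), float(full.rsquared)
    assert r2f >= r2b - 1e-12, "nested models: full R^2 below base"
    inc = max(0.0, r2f - r2b)
    pct = 100.0 * inc / r2b if r2b > 0 else np.nan
    if r2b == 0:
        logger.warning("incremental_r2: base R^2 is 0; pct_increase undefined")
    return IncrementalFit(
        r2_base=r2b, r2_full=r2f, r2_increment=inc, pct_increase=pct,
        prs_beta=float(full.params[-1]), prs_se=float(full.bse[-1]),
        prs_p=float(full.pvalues[-1]), n=n,
    )


# ---------------------------------------------------------------------------
# decile stratification
# ---------------------------------------------------------------------------

@dataclass
class DecileReport:
    table: pd.DataFrame  # decile, n, mean, sd
    t: float
    df: int
    p: float
    cohens_d: float


def decile_assignments(prs, n_deciles: int = 10) -> np.ndarray:
    """Decile labels (1..n_deciles) by ascending PRS.

    Sizes differ by at most one; the remainder goes to the upper deciles.
    Ties in the PRS are broken by stable input order.
    """
    x = np.asarray(prs, dtype=np.float64)
    n = x.size
    order = np.argsort(x, kind="stable")
    base, rem = divmod(n, n_deciles)
    sizes = [base] * (n_deciles - rem) + [base + 1] * rem
    labels = np.empty(n, dtype=np.int64)
    start = 0
    for d, size in enumerate(sizes, start=1):
        labels[order[start:start + size]] = d
        start += size
    return labels


def summary_t(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> tuple[float, int, float]:
    """Pooled-variance two-sample t from summary statistics.

    Lets printed decile summaries (mean, SD, n per group) be audited without
    individual-level data.  Returns ``(t, df, p_two_sided)`` with
    ``t = (mean1 - mean2) / SE``.
    """
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("standard deviations must be positive")
    if n1 < 2 or n2 < 2:
        raise ValueError("group sizes must be >= 2")
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / df
    se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    t = (mean1 - mean2) / se
    return float(t), int(df), float(2.0 * stats.t.sf(abs(t), df))


def cohens_d_from_t(t: float, df: int) -> float:
    """Cohen's d via the pooled-t identity ``d = 2|t|/sqrt(df)``.

    Exact for equal group sizes under the pooled-variance t; used as the
    reporting convention for decile contrasts.
    """
    return 2.0 * abs(t) / np.sqrt(df)


def decile_contrast(
    prs, trait_values, n_deciles: int = 10, welch: bool = False
) -> DecileReport:
    """Mean/SD per PRS decile plus the decile 1 vs 10 two-sample t-test.

    The t statistic is signed as ``mean(decile 1) - mean(decile 10)`` over
    its standard error (negative when the top decile is higher); Cohen's d
    uses the pooled-t identity.  Pooled-variance (Student) t by default,
    Welch optionally.
    """
    x = np.asarray(prs, dtype=np.float64)
    y = np.asarray(trait_values, dtype=np.float64)
    if x.size < 2 * n_deciles:
        raise ValueError(f"need at least {2 * n_deciles} individuals")
    labels = decile_assignments(x, n_deciles)
    rows = []
    for d in range(1, n_deciles + 1):
        vals = y[labels == d]
        if vals.size == 0:
            raise ValueError(f"decile {d} is empty")
        rows.append((d, vals.size, float(vals.mean()), float(vals.std(ddof=1))))
    table = pd.DataFrame(rows, columns=["decile", "n", "mean", "sd"])
    lo = y[labels == 1]
    hi = y[labels == n_deciles]
    res = stats.ttest_ind(lo, hi, equal_var=not welch)
    df = int(lo.size + hi.size - 2) if not welch else int(res.df)
    t = float(res.statistic)
    return DecileReport(
        table=table, t=t, df=df, p=float(res.pvalue), cohens_d=cohens_d_from_t(t, df)
    )


# ---------------------------------------------------------------------------
# discrimination (AUC)
# ---------------------------------------------------------------------------

@dataclass
class DiscriminationReport:
    auc: float
    ci_low: float
    ci_high: float
    n_cases: int
    n_controls: int


def auc_mann_whitney(scores, labels, alpha: float = 0.05) -> DiscriminationReport:
    """Rank-based AUC, ``P(score_case > score_control) + 0.5 P(tie)``.

    The confidence interval uses the DeLong variance (case and control
    placement values), truncated to [0, 1].  Requires both classes.
    """
    s = np.asarray(scores, dtype=np.float64)
    lab = np.asarray(labels).astype(np.int64)
    keep = ~np.isnan(s)
    s, lab = s[keep], lab[keep]
    cases = s[lab == 1]
    controls = s[lab == 0]
    n1, n0 = cases.size, controls.size
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC requires both cases and controls")
    ranks = stats.rankdata(np.concatenate([cases, controls]))
    auc = (ranks[:n1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0)
    # DeLong placements: per-case fraction of controls beaten (+ half ties)
    v10 = (stats.rankdata(np.concatenate([cases, controls]))[:n1] -
           stats.rankdata(cases)) / n0
    v01 = 1.0 - (
        stats.rankdata(np.concatenate([controls, cases]))[:n0]
        - stats.rankdata(controls)
    ) / n1
    var = (np.var(v10, ddof=1) / n1 if n1 > 1 else 0.0) + (
        np.var(v01, ddof=1) / n0 if n0 > 1 else 0.0
    )
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    half = z * np.sqrt(var)
    return DiscriminationReport(
        auc=float(auc),
        ci_low=float(max(0.0, auc - half)),
        ci_high=float(min(1.0, auc + half)),
        n_cases=n1,
        n_controls=n0,
    )


# ---------------------------------------------------------------------------
# correlation structure
# ---------------------------------------------------------------------------

def prs_correlation_matrix(scores: pd.DataFrame) -> pd.DataFrame:
    """Pairwise-complete Pearson correlations between pathway PRS vectors.

    Zero-variance vectors produce NaN rows/columns (flagged by a warning);
    the diagonal is 1 for non-degenerate vectors.
    """
    if scores.shape[1] < 2:
        raise ValueError("need at least two score vectors")
    degenerate = [c for c in scores.columns if scores[c].dropna().std() == 0]
    if degenerate:
        logger.warning(
            "prs_correlation_matrix: zero-variance vector(s) %s", degenerate
        )
    return scores.corr(method="pearson", min_periods=2)
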