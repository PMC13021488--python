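"""Phenotype preparation, QC filters, principal components, discovery GWAS."""

from __future__ import annotations

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pathprs import assoc

from conftest import random_genotypes, toy_variants


# ---------------------------------------------------------------------------
# medication adjustment / traits / hypertension
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "sbp, dbp, med, expected",
    [
        (140.0, 90.0, 1, (155.0, 100.0)),
        (140.0, 90.0, 0, (140.0, 90.0)),
        (120.5, 80.5, 1, (135.5, 90.5)),
    ],
)
def test_medication_adjustment(sbp, dbp, med, expected):
    got = assoc.adjust_medication([sbp], [dbp], [med])
    assert (got[0][0], got[1][0]) == expected


def test_missing_medication_status_is_an_error():
    with pytest.raises(ValueError, match="med_use"):
        assoc.adjust_medication([120.0], [80.0], [np.nan])


def test_derived_traits():
    pp, map_ = assoc.derive_traits([120.0, 100.0], [80.0, 100.0])
    assert pp[0] == 40.0 and math.isclose(map_[0], 280.0 / 3.0)
    assert pp[1] == 0.0 and map_[1] == 100.0  # degenerate SBP == DBP
    # cohort-mean consistency: 159.7 - 101.3 = 58.4 (printed PP matches)
    pp2, _ = assoc.derive_traits([159.7], [101.3])
    assert round(pp2[0], 1) == 58.4


@pytest.mark.parametrize(
    "sbp, dbp, med, expected",
    [
        (139.9, 89.9, 0, 0),
        (140.0, 89.0, 0, 1),  # SBP threshold inclusive
        (139.0, 90.0, 0, 1),  # DBP threshold inclusive
        (130.0, 85.0, 1, 1),  # medication alone
    ],
)
def test_hypertension_definition(sbp, dbp, med, expected):
    assert assoc.classify_hypertension([sbp], [dbp], [med])[0] == expected


def test_prepare_phenotypes_pipeline_order():
    """Adjustment precedes trait derivation; HTN uses raw readings."""
    phen = pd.DataFrame(
        {
            "sample_id": ["a", "b"],
            "sbp": [130.0, 150.0],
            "dbp": [85.0, 95.0],
            "age": [50.0, 60.0],
            "sex": [0, 1],
            "med_use": [1, 0],
        }
    )
    out = assoc.prepare_phenotypes(phen)
    assert out.loc[0, "sbp_adj"] == 145.0 and out.loc[0, "dbp_adj"] == 95.0
    assert out.loc[0, "pp_adj"] == 50.0  # derived from adjusted values
    assert out.loc[0, "htn"] == 1  # via medication, not the adjusted 145
    assert out.loc[1, "htn"] == 1  # raw SBP 150 >= 140


# ---------------------------------------------------------------------------
# HWE exact test and QC
# ---------------------------------------------------------------------------

def hwe_enumeration_oracle(n_het: int, n_hom1: int, n_hom2: int) -> float:
    """Exact HWE p by full enumeration of heterozygote counts.

    P(h | n, rare) ∝ binom stuff computed from log-factorials; sums the
    probabilities of all configurations no more likely than the observed.
    """
    n = n_het + n_hom1 + n_hom2
    rare = 2 * min(n_hom1, n_hom2) + n_het
    lf = [math.lgamma(i + 1) for i in range(2 * n + 1)]

    def log_prob(h):
        if (rare - h) % 2:
            return -np.inf
        hr = (rare - h) // 2
        hc = n - h - hr
        if hr < 0 or hc < 0:
            return -np.inf
        return (
            lf[n] - lf[hr] - lf[h] - lf[hc]
            + h * math.log(2)
            + lf[rare] + lf[2 * n - rare] - lf[2 * n]
        )

    logs = np.array([log_prob(h) for h in range(rare + 1)])
    probs = np.exp(logs - logs[np.isfinite(logs)].max())
    probs[~np.isfinite(logs)] = 0.0
    probs /= probs.sum()
    p_obs = probs[n_het]
    return float(probs[probs <= p_obs * (1 + 1e-12)].sum())


@pytest.mark.parametrize(
    "het, hom1, hom2",
    [(57, 21, 22), (100, 50, 50), (200, 0, 0), (10, 90, 0), (0, 50, 50), (13, 7, 80)],
)
def test_hwe_exact_matches_enumeration(het, hom1, hom2):
    got = assoc.hwe_exact_p(het, hom1, hom2)
    want = hwe_enumeration_oracle(het, hom1, hom2)
    assert got == pytest.approx(want, rel=1e-9, abs=1e-12)


def test_qc_maf_boundary():
    rng = np.random.default_rng(0)
    n = 1000
    d = np.column_stack(
        [
            np.repeat([1.0, 0.0], [98, n - 98]),   # MAF 0.049 -> removed
            np.repeat([1.0, 0.0], [100, n - 100]),  # MAF 0.050 -> retained
            np.zeros(n),                            # monomorphic -> removed
            rng.binomial(2, 0.3, n).astype(float),
        ]
    )
    variants = toy_variants([1000, 2000, 3000, 4000])
    kept, dk, log = assoc.qc_filter(variants, d, hwe_alpha=0.0)
    assert kept["snp_id"].tolist() == ["s1", "s3"]
    assert log.n_maf == 2


def test_qc_hwe_rule_removes_all_heterozygote_snp():
    rng = np.random.default_rng(1)
    n = 200
    cols = [rng.binomial(2, 0.4, n).astype(float) for _ in range(4)]
    cols.insert(2, np.ones(n))  # every individual heterozygous: extreme HWE violation
    d = np.column_stack(cols)
    variants = toy_variants([1000, 2000, 3000, 4000, 5000])
    kept, _, log = assoc.qc_filter(variants, d, hwe_alpha=1e-6)
    assert "s2" not in kept["snp_id"].tolist()
    assert log.n_hwe == 1 and log.n_retained == 4


def test_qc_missingness_rule():
    rng = np.random.default_rng(2)
    n = 200
    good = rng.binomial(2, 0.3, n).astype(float)
    bad = good.copy()
    bad[: int(0.2 * n)] = np.nan
    d = np.column_stack([good, bad])
    kept, _, log = assoc.qc_filter(toy_variants([1, 500_000]), d)
    assert kept["snp_id"].tolist() == ["s0"]
    assert log.n_missing == 1


def test_qc_everything_removed_is_an_error():
    d = np.zeros((50, 2))
    with pytest.raises(ValueError):
        assoc.qc_filter(toy_variants([1, 2]), d)


# ---------------------------------------------------------------------------
# principal components
# ---------------------------------------------------------------------------

def test_pc1_separates_planted_populations():
    rng = np.random.default_rng(3)
    n, m = 500, 200
    labels = np.repeat([0, 1], n // 2)
    freqs = np.column_stack(
        [rng.uniform(0.2, 0.4, m), rng.uniform(0.4, 0.6, m)]
    )  # freq gap 0.2
    d = rng.binomial(2, freqs[:, labels].T).astype(float)
    pcs = assoc.compute_pcs(d, k=2, ld_prune=False)
    r = np.corrcoef(pcs[:, 0], labels)[0, 1]
    assert abs(r) > 0.9


def test_pcs_orthogonal_unit_variance():
    rng = np.random.default_rng(4)
    d = random_genotypes(rng, 120, rng.uniform(0.1, 0.5, 80))
    pcs = assoc.compute_pcs(d, k=5, ld_prune=False)
    gram = pcs.T @ pcs / len(pcs)
    np.testing.assert_allclose(np.diag(gram), 1.0, atol=1e-10)
    off = gram - np.diag(np.diag(gram))
    assert np.abs(off).max() < 1e-8


def test_rank_one_recovery():
    rng = np.random.default_rng(5)
    v = rng.standard_normal(60)
    load = rng.standard_normal(30)
    X = np.outer(v, load)
    pcs = assoc.compute_pcs(X, k=1, ld_prune=False)
    r = np.corrcoef(pcs[:, 0], v)[0, 1]
    assert abs(abs(r) - 1.0) < 1e-10


def test_k_exceeding_rank_raises():
    X = np.outer(np.arange(10.0), np.ones(4)) + np.random.default_rng(0).normal(
        0, 1e-9, (10, 4)
    )
    with pytest.raises(ValueError):
        assoc.compute_pcs(np.zeros((3, 5)), k=4)
    del X


# ---------------------------------------------------------------------------
# GWAS
# ---------------------------------------------------------------------------

def normal_equations_oracle(y, d, Z):
    """Independent per-SNP OLS via explicit normal equations."""
    X = np.column_stack([np.ones(len(y)), Z, d])
    XtX = X.T @ X
    beta = np.linalg.solve(XtX, X.T @ y)
    resid = y - X @ beta
    df = len(y) - X.shape[1]
    sigma2 = resid @ resid / df
    se = np.sqrt(sigma2 * np.linalg.inv(XtX)[-1, -1])
    t = beta[-1] / se
    return beta[-1], se, 2 * stats.t.sf(abs(t), df), df


def simulate_gwas_data(seed=0, n=500, m=12, beta=0.8):
    rng = np.random.default_rng(seed)
    d = random_genotypes(rng, n, rng.uniform(0.1, 0.5, m))
    age = rng.normal(50, 10, n)
    sex = rng.integers(0, 2, n)
    cov = pd.DataFrame({"age": age, "sex": sex})
    y = 140 + beta * d[:, 0] + 0.4 * age + 2.0 * sex + rng.normal(0, 8, n)
    return d, y, cov


def test_gwas_matches_normal_equations_oracle():
    d, y, cov = simulate_gwas_data()
    res = assoc.gwas_additive(d, y, cov, toy_variants(range(0, 12_000, 1000)))
    Z = cov.to_numpy()
    for j in range(d.shape[1]):
        b, se, p, df = normal_equations_oracle(y, d[:, j], Z)
        row = res.iloc[j]
        assert row["beta"] == pytest.approx(abs(b), abs=1e-8)
        assert row["se"] == pytest.approx(se, abs=1e-8)
        assert row["p"] == pytest.approx(p, rel=1e-8)
        assert row["risk_allele"] == ("G" if b >= 0 else "A")
        assert df == row["n_used"] - (cov.shape[1] + 2)


def test_gwas_recovers_planted_effect_within_3se():
    d, y, cov = simulate_gwas_data(seed=1, n=2295, beta=0.8)
    res = assoc.gwas_additive(d, y, cov, toy_variants(range(0, 12_000, 1000)))
    row = res.iloc[0]
    assert abs(row["beta"] - 0.8) < 3 * row["se"]


def test_allele_coding_flip_negates_beta_identical_p():
    d, y, cov = simulate_gwas_data(seed=2)
    variants = toy_variants(range(0, 12_000, 1000))
    res1 = assoc.gwas_additive(d, y, cov, variants)
    flipped = variants.copy()
    flipped["ref"], flipped["alt"] = variants["alt"], variants["ref"]
    res2 = assoc.gwas_additive(2.0 - d, y, cov, flipped)
    np.testing.assert_allclose(res1["beta"], res2["beta"], atol=1e-10)
    np.testing.assert_allclose(res1["p"], res2["p"], atol=1e-12)
    assert (res1["risk_allele"] == res2["risk_allele"]).all()


def test_gwas_handles_missing_dosages_per_snp():
    d, y, cov = simulate_gwas_data(seed=3)
    d[:40, 0] = np.nan
    res = assoc.gwas_additive(d, y, cov, toy_variants(range(0, 12_000, 1000)))
    row = res.iloc[0]
    assert row["n_used"] == len(y) - 40
    mask = ~np.isnan(d[:, 0])
    b, se, p, _ = normal_equations_oracle(y[mask], d[mask, 0], cov.to_numpy()[mask])
    assert row["beta"] == pytest.approx(abs(b), abs=1e-8)
    assert row["p"] == pytest.approx(p, rel=1e-6)


def test_collinear_covariates_raise():
    d, y, cov = simulate_gwas_data(seed=4)
    cov["age2"] = 2.0 * cov["age"]
    with pytest.raises(ValueError, match="collinear"):
        assoc.gwas_additive(d, y, cov, toy_variants(range(0, 12_000, 1000)))


def test_zero_variance_snp_skipped():
    d, y, cov = simulate_gwas_data(seed=5)
    d[:, 2] = 1.0
    res = assoc.gwas_additive(d, y, cov, toy_variants(range(0, 12_000, 1000)))
    assert "s2" not in res["snp_id"].tolist()
    assert len(res) == d.shape[1] - 1


def test_null_type_one_error_calibrated_small():
    rng = np.random.default_rng(6)
    n, m = 800, 400
    d = random_genotypes(rng, n, rng.uniform(0.1, 0.5, m))
    y = rng.normal(0, 1, n)
    cov = pd.DataFrame({"age": rng.normal(50, 10, n), "sex": rng.integers(0, 2, n)})
    res = assoc.gwas_additive(d, y, cov, toy_variants(range(0, m * 1000, 1000)))
    frac = (res["p"] < 0.05).mean()
    lo, hi = stats.binom.ppf([0.005, 0.995], m, 0.05) / m
    assert lo <= frac <= hi
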