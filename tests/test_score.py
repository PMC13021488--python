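"""C+T model construction, PLINK-default scoring, threshold selection."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from pathprs import evaluate
from pathprs.ldclump import ClumpedSet
from pathprs.score import (
    THRESHOLD_GRID,
    PrsModel,
    build_model,
    scan_thresholds,
    score_individuals,
)

from conftest import toy_variants


def make_assoc(n=10, seed=0):
    rng = np.random.default_rng(seed)
    v = toy_variants(range(1000, 1000 + 1000 * n, 1000))
    return pd.DataFrame(
        {
            "snp_id": v["snp_id"],
            "chrom": v["chrom"],
            "pos": v["pos"],
            "ref": v["ref"],
            "alt": v["alt"],
            "risk_allele": np.where(rng.random(n) < 0.5, "G", "A"),
            "beta": rng.uniform(0.1, 1.0, n),
            "p": rng.uniform(1e-5, 0.6, n),
        }
    ), v


def clumpset(ids, assoc):
    sub = assoc[assoc["snp_id"].isin(ids)]
    return ClumpedSet(
        index_snps=sub[["snp_id", "chrom", "pos", "p"]].reset_index(drop=True),
        members={i: [] for i in ids},
    )


# ---------------------------------------------------------------------------
# model building
# ---------------------------------------------------------------------------

def test_model_is_triple_intersection():
    assoc, v = make_assoc()
    clumped = clumpset(assoc["snp_id"].iloc[:6].tolist(), assoc)
    snp_map = {"pw": np.array([0, 1, 2, 8]), "combined": np.arange(10)}
    model = build_model(assoc, clumped, snp_map, v, "sbp", "pw", 0.05)
    expected = {
        s for s in assoc["snp_id"].iloc[:6]
        if s in set(v["snp_id"].iloc[[0, 1, 2, 8]])
        and float(assoc.loc[assoc.snp_id == s, "p"].iloc[0]) <= 0.05
    }
    assert set(model.snps["snp_id"]) == expected


def test_combined_model_count_matches_bruteforce():
    assoc, v = make_assoc(seed=3)
    clumped = clumpset(assoc["snp_id"].tolist(), assoc)
    snp_map = {"combined": np.arange(len(assoc))}
    model = build_model(assoc, clumped, snp_map, v, "sbp", "combined", 0.05)
    assert model.n_snps == int((assoc["p"] <= 0.05).sum())


def test_snp_in_two_pathways_once_in_combined():
    assoc, v = make_assoc(seed=4)
    assoc.loc[0, "p"] = 1e-4
    clumped = clumpset(assoc["snp_id"].tolist(), assoc)
    snp_map = {
        "pw1": np.array([0, 1]),
        "pw2": np.array([0, 2]),
        "combined": np.array([0, 1, 2]),
    }
    models = {
        pid: build_model(assoc, clumped, snp_map, v, "sbp", pid, 0.05)
        for pid in ("pw1", "pw2", "combined")
    }
    s0 = v["snp_id"].iloc[0]
    assert s0 in set(models["pw1"].snps["snp_id"])
    assert s0 in set(models["pw2"].snps["snp_id"])
    assert (models["combined"].snps["snp_id"] == s0).sum() == 1


def test_threshold_below_all_p_values_gives_empty_flagged_model(caplog):
    assoc, v = make_assoc(seed=5)
    assoc["p"] = 0.4
    clumped = clumpset(assoc["snp_id"].tolist(), assoc)
    with caplog.at_level("INFO"):
        model = build_model(
            assoc, clumped, {"combined": np.arange(10)}, v, "sbp", "combined", 0.001
        )
    assert model.is_empty
    assert any("empty model" in r.message for r in caplog.records)


def test_unknown_pathway_raises():
    assoc, v = make_assoc()
    clumped = clumpset(assoc["snp_id"].tolist(), assoc)
    with pytest.raises(KeyError, match="nope"):
        build_model(assoc, clumped, {"combined": np.arange(10)}, v, "sbp", "nope", 0.05)


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

def model_of(v, rows, weights, risk=None):
    return PrsModel(
        trait="sbp", pathway_id="combined", threshold=0.05,
        snps=pd.DataFrame(
            {
                "snp_id": v["snp_id"].iloc[rows].to_numpy(),
                "risk_allele": risk if risk is not None else v["alt"].iloc[rows].to_numpy(),
                "weight": weights,
            }
        ),
    )


def test_single_snp_average_score():
    v = toy_variants([1000])
    model = model_of(v, [0], [0.5])
    d = np.array([[2.0], [1.0], [0.0]])
    scores = score_individuals(model, d, v)
    np.testing.assert_allclose(scores["prs"], [0.5, 0.25, 0.0])


def test_all_zero_weights_give_zero_scores():
    v = toy_variants([1000, 2000])
    model = model_of(v, [0, 1], [0.0, 0.0])
    d = np.random.default_rng(0).binomial(2, 0.4, (6, 2)).astype(float)
    scores = score_individuals(model, d, v)
    np.testing.assert_allclose(scores["prs"], 0.0)


def test_toy_panel_with_missing_genotype_matches_hand_computation():
    """5 SNPs x 4 individuals, one missing genotype, risk freq 0.25."""
    v = toy_variants([1000, 2000, 3000, 4000, 5000])
    w = np.array([0.5, 1.0, 0.25, 0.75, 2.0])
    model = model_of(v, [0, 1, 2, 3, 4], w)
    d = np.array(
        [
            [2.0, 1.0, 0.0, 1.0, 2.0],
            [np.nan, 0.0, 1.0, 2.0, 0.0],
            [1.0, 1.0, 1.0, 1.0, 1.0],
            [0.0, 2.0, 2.0, 0.0, 1.0],
        ]
    )
    freqs = np.array([0.25, 0.5, 0.5, 0.5, 0.5])  # ALT freqs supplied externally
    scores = score_individuals(model, d, v, allele_freqs=freqs)
    # brute-force oracle of score_i = sum_j w_j d_ij / (2 m_i), imputed d = 2*0.25
    d_imp = d.copy()
    d_imp[1, 0] = 0.5
    expected = (d_imp * w).sum(axis=1) / (2 * 5)
    np.testing.assert_allclose(scores["prs"], expected, atol=1e-12)
    assert scores["n_snps_used"].tolist() == [5, 5, 5, 5]


def test_no_imputation_mode_uses_nonmissing_count():
    v = toy_variants([1000, 2000])
    model = model_of(v, [0, 1], [1.0, 1.0])
    d = np.array([[2.0, np.nan]])
    scores = score_individuals(model, d, v, allele_freqs=np.array([0.5, 0.5]),
                               impute_missing=False)
    assert scores["prs"].iloc[0] == pytest.approx(2.0 / (2 * 1))
    assert scores["n_snps_used"].iloc[0] == 1


def test_allele_coding_flip_invariance():
    rng = np.random.default_rng(1)
    v = toy_variants([1000, 2000, 3000])
    d = rng.binomial(2, 0.4, (20, 3)).astype(float)
    model = model_of(v, [0, 1, 2], [0.5, 1.0, 0.2], risk=["G", "A", "G"])
    s1 = score_individuals(model, d, v)
    flipped = v.copy()
    flipped["ref"], flipped["alt"] = v["alt"], v["ref"]
    s2 = score_individuals(model, 2.0 - d, flipped)
    np.testing.assert_allclose(s1["prs"], s2["prs"], atol=1e-12)


def test_scoring_linearity_under_concatenation():
    """Score of the union = m-weighted average of the part scores."""
    rng = np.random.default_rng(2)
    v = toy_variants(range(1000, 7000, 1000))
    d = rng.binomial(2, 0.3, (15, 6)).astype(float)
    w = rng.uniform(0.1, 1.0, 6)
    full = score_individuals(model_of(v, list(range(6)), w), d, v)["prs"]
    part1 = score_individuals(model_of(v, [0, 1], w[:2]), d, v)["prs"]
    part2 = score_individuals(model_of(v, [2, 3, 4, 5], w[2:]), d, v)["prs"]
    np.testing.assert_allclose(full, (2 * part1 + 4 * part2) / 6, atol=1e-12)


def test_sum_mode_is_average_times_2m():
    rng = np.random.default_rng(3)
    v = toy_variants([1000, 2000])
    d = rng.binomial(2, 0.4, (8, 2)).astype(float)
    model = model_of(v, [0, 1], [0.3, 0.7])
    avg = score_individuals(model, d, v, average=True)["prs"]
    total = score_individuals(model, d, v, average=False)["prs"]
    np.testing.assert_allclose(total, avg * 4, atol=1e-12)


def test_empty_model_scoring_raises():
    v = toy_variants([1000])
    empty = PrsModel("sbp", "combined", 0.05,
                     pd.DataFrame(columns=["snp_id", "risk_allele", "weight"]))
    with pytest.raises(ValueError, match="empty"):
        score_individuals(empty, np.zeros((3, 1)), v)


# ---------------------------------------------------------------------------
# threshold scan
# ---------------------------------------------------------------------------

def scan_setup(seed=0, n=300, m=60, n_causal=8):
    """Discovery assoc + validation cohort with signal at small p."""
    rng = np.random.default_rng(seed)
    v = toy_variants(range(1000, 1000 + 400_000 * m, 400_000))
    d = rng.binomial(2, 0.4, (n, m)).astype(float)
    w = np.zeros(m)
    w[:n_causal] = rng.uniform(0.5, 1.0, n_causal)
    y = d @ w + rng.normal(0, 2.0, n)
    p = np.concatenate([
        rng.uniform(1e-6, 5e-4, n_causal),        # causal: p <= 1e-3
        rng.uniform(2e-3, 1.0, m - n_causal),     # null SNPs spread upward
    ])
    assoc = pd.DataFrame(
        {
            "snp_id": v["snp_id"], "chrom": v["chrom"], "pos": v["pos"],
            "ref": v["ref"], "alt": v["alt"], "risk_allele": v["alt"],
            "beta": np.where(w > 0, w, rng.uniform(0.05, 0.3, m)), "p": p,
        }
    )
    cov = pd.DataFrame({"age": rng.normal(50, 10, n), "sex": rng.integers(0, 2, n)})
    return assoc, v, d, y, cov


def build_grid_models(assoc, v):
    clumped = clumpset(assoc["snp_id"].tolist(), assoc)
    snp_map = {"combined": np.arange(len(v))}
    return {
        thr: build_model(assoc, clumped, snp_map, v, "sbp", "combined", thr)
        for thr in THRESHOLD_GRID
    }


def test_scan_grid_is_exactly_the_seven_thresholds():
    assoc, v, d, y, cov = scan_setup()
    scan, selected = scan_thresholds(build_grid_models(assoc, v), d, v, y, cov)
    assert scan["threshold"].tolist() == [
        0.0010, 0.0025, 0.0050, 0.0075, 0.0100, 0.0250, 0.0500
    ]
    assert np.all(np.diff(scan["n_snps"]) >= 0)  # non-decreasing in threshold
    assert selected in THRESHOLD_GRID


def test_scan_rejects_wrong_grid():
    assoc, v, d, y, cov = scan_setup()
    models = build_grid_models(assoc, v)
    del models[0.05]
    with pytest.raises(ValueError, match="seven"):
        scan_thresholds(models, d, v, y, cov)


def test_empty_threshold_scores_zero_increment():
    assoc, v, d, y, cov = scan_setup(seed=2)
    assoc.loc[assoc["p"] < 2e-3, "p"] = 3e-3  # nothing below the two smallest cuts
    scan, _ = scan_thresholds(build_grid_models(assoc, v), d, v, y, cov)
    assert scan.loc[scan["threshold"] == 0.0010, "r2_increment"].iloc[0] == 0.0
    assert scan.loc[scan["threshold"] == 0.0010, "n_snps"].iloc[0] == 0


def test_all_empty_models_raise():
    assoc, v, d, y, cov = scan_setup(seed=3)
    assoc["p"] = 0.9
    with pytest.raises(ValueError, match="empty"):
        scan_thresholds(build_grid_models(assoc, v), d, v, y, cov)


def test_standardized_and_raw_prs_equivalent_incremental_r2():
    assoc, v, d, y, cov = scan_setup(seed=4)
    model = build_grid_models(assoc, v)[0.05]
    scores = score_individuals(model, d, v)
    fit_raw = evaluate.incremental_r2(y, scores["prs"], cov)
    fit_std = evaluate.incremental_r2(y, scores["prs_std"], cov)
    assert fit_raw.r2_increment == pytest.approx(fit_std.r2_increment, abs=1e-12)
    assert fit_raw.prs_p == pytest.approx(fit_std.prs_p, rel=1e-9)
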