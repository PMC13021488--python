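"""Shared fixtures: small synthetic cohorts and toy pathway annotations."""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import pytest

from pathprs.pathways import GeneInterval, PathwaySet
from pathprs.synthdata import SimConfig, simulate_cohorts


def make_config(**overrides) -> SimConfig:
    base = dict(
        n_discovery=400,
        n_validation=300,
        n_target=200,
        n_blocks=22,
        snps_per_block=10,
        seed=7,
        causal_pathways=("hsa04024",),
    )
    base.update(overrides)
    return SimConfig(**base)


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    return make_config()


@pytest.fixture(scope="session")
def small_cohorts(small_config):
    """Three small cohorts with signal concentrated in the cAMP pathway."""
    return simulate_cohorts(small_config)


@pytest.fixture()
def toy_pathway_set() -> PathwaySet:
    """Two pathways over three genes on chromosome 1."""
    return PathwaySet(
        pathways={
            "pw1": ("first", frozenset({"gA", "gB"})),
            "pw2": ("second", frozenset({"gB", "gC"})),
        },
        intervals={
            "gA": [GeneInterval("gA", "1", 400, 600)],
            "gB": [GeneInterval("gB", "1", 1_000, 1_500)],
            "gC": [GeneInterval("gC", "1", 5_000, 5_800)],
        },
    )


def toy_variants(positions, chrom="1") -> pd.DataFrame:
    return pd.DataFrame(
        {
            "snp_id": [f"s{i}" for i in range(len(positions))],
            "chrom": chrom,
            "pos": list(positions),
            "ref": "A",
            "alt": "G",
        }
    )


def replace_config(cfg: SimConfig, **kw) -> SimConfig:
    return dataclasses.replace(cfg, **kw)


def random_genotypes(rng: np.random.Generator, n: int, freqs) -> np.ndarray:
    """Independent binomial(2, p) dosages, one column per frequency."""
    freqs = np.asarray(freqs, dtype=float)
    return rng.binomial(2, freqs, size=(n, freqs.size)).astype(np.float64)
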