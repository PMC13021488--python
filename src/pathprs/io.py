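"""Readers and writers for the pipeline's file formats.

Genotypes travel as VCF 4.2 with both GT and DS FORMAT fields (DS = dosage
of the ALT allele); phenotypes, association results, models and reports are
plain TSV.  VCF parsing goes through :mod:`cyvcf2`.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from cyvcf2 import VCF

PHENOTYPE_COLUMNS = ["sample_id", "sbp", "dbp", "age", "sex", "med_use"]


def write_vcf(
    path: str | Path,
    dosages: np.ndarray,
    variants: pd.DataFrame,
    sample_ids: Sequence[str],
) -> None:
    """Write a dosage matrix as VCF 4.2 with GT and DS per sample.

    GT is derived from the rounded dosage; missing dosages (NaN) become
    ``./.`` with DS ``.``.
    """
    path = Path(path)
    n, m = dosages.shape
    if m != len(variants) or n != len(sample_ids):
        raise ValueError("dosage matrix not aligned to variants/samples")
    gt_codes = {0: "0/0", 1: "0/1", 2: "1/1"}
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=pathprs\n")
        for chrom in pd.unique(variants["chrom"]):
            sub = variants.loc[variants["chrom"] == chrom, "pos"]
            fh.write(f"##contig=<ID={chrom},length={int(sub.max()) + 1000}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            '##FORMAT=<ID=DS,Number=1,Type=Float,Description="Dosage of ALT allele">\n'
        )
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(sample_ids)
            + "\n"
        )
        chroms = variants["chrom"].astype(str).to_numpy()
        poss = variants["pos"].to_numpy()
        ids = variants["snp_id"].astype(str).to_numpy()
        refs = variants["ref"].astype(str).to_numpy()
        alts = variants["alt"].astype(str).to_numpy()
        for j in range(m):
            col = dosages[:, j]
            cells = []
            for d in col:
                if np.isnan(d):
                    cells.append("./.:.")
                else:
                    gt = gt_codes[int(round(min(max(d, 0.0), 2.0)))]
                    cells.append(f"{gt}:{d:.6g}")
            fh.write(
                f"{chroms[j]}\t{poss[j]}\t{ids[j]}\t{refs[j]}\t{alts[j]}\t.\t.\t.\t"
                "GT:DS\t" + "\t".join(cells) + "\n"
            )


def read_vcf(path: str | Path) -> tuple[np.ndarray, pd.DataFrame, list[str]]:
    """Read a VCF into ``(dosages, variants, sample_ids)``.

    Dosages come from the DS FORMAT field when present, otherwise from hard
    genotypes; missing genotypes are NaN.  Multi-allelic records are rejected.
    """
    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    rows = []
    cols = []
    for v in vcf:
        if len(v.ALT) != 1:
            raise ValueError(f"{path}: multi-allelic record at {v.CHROM}:{v.POS}")
        rows.append((v.ID, str(v.CHROM), int(v.POS), v.REF, v.ALT[0]))
        ds = v.format("DS")
        if ds is not None:
            col = np.asarray(ds, dtype=np.float64).reshape(-1)
            col = np.where(np.isfinite(col), col, np.nan)
        else:
            gt = np.asarray(v.gt_types, dtype=np.float64)
            col = np.where(gt >= 3, np.nan, gt)
        cols.append(col)
    vcf.close()
    variants = pd.DataFrame(rows, columns=["snp_id", "chrom", "pos", "ref", "alt"])
    dosages = (
        np.column_stack(cols) if cols else np.empty((len(samples), 0), dtype=np.float64)
    )
    with np.errstate(invalid="ignore"):
        freq = np.nanmean(dosages, axis=0) / 2.0 if cols else np.array([])
    variants["maf"] = np.minimum(freq, 1.0 - freq) if cols else freq
    return dosages, variants, samples


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    """Read a phenotype TSV; requires the canonical column set."""
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = set(PHENOTYPE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing phenotype columns {sorted(missing)}")
    return df


def read_dosage_tsv(path: str | Path) -> tuple[np.ndarray, pd.DataFrame, list[str]]:
    """Read a plain dosage matrix TSV (snp_id, chrom, pos, ref, alt, samples...)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    meta_cols = ["snp_id", "chrom", "pos", "ref", "alt"]
    variants = df[meta_cols].copy()
    variants["chrom"] = variants["chrom"].astype(str)
    samples = [c for c in df.columns if c not in meta_cols]
    dosages = df[samples].to_numpy(dtype=np.float64).T
    with np.errstate(invalid="ignore"):
        freq = np.nanmean(dosages, axis=0) / 2.0
    variants["maf"] = np.minimum(freq, 1.0 - freq)
    return dosages, variants, samples


def write_tsv_with_provenance(
    df: pd.DataFrame, path: str | Path, provenance: dict | None = None
) -> None:
    """Write a TSV with ``# key=value`` provenance header lines."""
    path = Path(path)
    with path.open("w") as fh:
        for k, v in (provenance or {}).items():
            fh.write(f"# {k}={v}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def config_hash(obj) -> str:
    """Stable short hash of a configuration mapping (for provenance headers)."""
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]
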