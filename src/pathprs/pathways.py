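"""Gene-set (pathway) definitions and coordinate-based SNP-to-pathway mapping.

Pathways are named gene sets (GMT format); genes carry genomic intervals
(BED-like file, GRCh37-style coordinates).  A SNP belongs to a pathway when
its position falls inside any member gene's interval (optionally extended by
a symmetric flank) on the same chromosome.  The union of all pathways is
exposed as the pseudo-pathway ``"combined"``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .exceptions import ParseError

logger = logging.getLogger(__name__)

COMBINED = "combined"

#: KEGG identifiers and names of the eleven pathways targeted by common
#: first-line antihypertensive drug classes (beta-blockers, calcium-channel
#: blockers, ACE inhibitors, angiotensin-receptor blockers).
ANTIHYPERTENSIVE_PATHWAYS: dict[str, str] = {
    "hsa04261": "Adrenergic signaling in cardiomyocytes",
    "hsa04925": "Aldosterone synthesis and secretion",
    "hsa04020": "Calcium signaling",
    "hsa04260": "Cardiac muscle contraction",
    "hsa04010": "MAPK signaling pathway",
    "hsa04080": "Neuroactive ligand receptor interaction",
    "hsa04614": "Renin-angiotensin system",
    "hsa04924": "Renin secretion",
    "hsa04022": "cGMP-PKG signaling pathway",
    "hsa04024": "cAMP signaling pathway",
    "hsa04270": "Vascular smooth muscle contraction",
}


def normalize_chrom(chrom: str) -> str:
    """Normalize a chromosome label: strip a leading ``chr`` and upper-case."""
    c = str(chrom).strip()
    if c.lower().startswith("chr"):
        c = c[3:]
    return c.upper()


@dataclass(frozen=True)
class GeneInterval:
    """A gene body on a chromosome, 1-based inclusive endpoints.

    ``flank_bp`` is an optional per-gene symmetric extension applied at
    mapping time in addition to any global flank.
    """

    gene_symbol: str
    chrom: str
    start: int
    end: int
    flank_bp: int = 0

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ParseError(
                f"gene {self.gene_symbol}: start {self.start} > end {self.end}"
            )
        if self.flank_bp < 0:
            raise ParseError(f"gene {self.gene_symbol}: negative flank_bp")


@dataclass
class PathwaySet:
    """Named gene sets plus a gene -> interval map.

    ``pathways`` maps pathway id to ``(name, frozenset of gene symbols)``.
    ``intervals`` maps upper-cased gene symbol to its interval list (a symbol
    may map to several intervals, e.g. split annotations).
    """

    pathways: dict[str, tuple[str, frozenset[str]]]
    intervals: dict[str, list[GeneInterval]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.intervals = {k.upper(): v for k, v in self.intervals.items()}

    @property
    def pathway_ids(self) -> list[str]:
        return list(self.pathways)

    def genes(self, pathway_id: str) -> frozenset[str]:
        return self.pathways[pathway_id][1]

    @property
    def combined_genes(self) -> frozenset[str]:
        """Deduplicated union of all member gene sets."""
        return combine_pathways(self.pathways)

    def intervals_for(self, gene_symbol: str) -> list[GeneInterval]:
        return self.intervals.get(gene_symbol.strip().upper(), [])


def read_gmt(path: str | Path) -> dict[str, tuple[str, frozenset[str]]]:
    """Read a GMT file (pathway id, description, member genes...).

    Gene symbols are trimmed and deduplicated within each set (a duplicate
    triggers a logged warning).  Lines with fewer than three tab-separated
    fields raise :class:`ParseError` naming the offending line.
    """
    path = Path(path)
    out: dict[str, tuple[str, frozenset[str]]] = {}
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected >= 3 tab-separated fields")
            pid, name = fields[0].strip(), fields[1].strip()
            genes = [g.strip() for g in fields[2:] if g.strip()]
            uniq = frozenset(genes)
            if len(uniq) < len(genes):
                logger.warning(
                    "%s:%d: pathway %s lists %d duplicate gene(s); deduplicated",
                    path, lineno, pid, len(genes) - len(uniq),
                )
            if pid in out:
                raise ParseError(f"{path}:{lineno}: duplicate pathway id {pid}")
            out[pid] = (name, uniq)
    if not out:
        logger.warning("%s: empty GMT file", path)
    return out


def write_gmt(pathways: Mapping[str, tuple[str, frozenset[str]]], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for pid, (name, genes) in pathways.items():
            fh.write("\t".join([pid, name, *sorted(genes)]) + "\n")


def combine_pathways(pathways: Mapping[str, tuple[str, frozenset[str]]]) -> frozenset[str]:
    """Union of all pathway gene sets (case-preserving, duplicate-free)."""
    if not pathways:
        raise ValueError("combine_pathways requires a non-empty pathway map")
    out: set[str] = set()
    for _, genes in pathways.values():
        out |= genes
    return frozenset(out)


def read_gene_intervals(
    path: str | Path, one_based: bool | None = None
) -> dict[str, list[GeneInterval]]:
    """Read a BED-like gene interval file: chrom, start, end, gene_symbol.

    Coordinate convention is declared either by ``one_based`` or by a header
    line ``#coordinates=1-based-inclusive`` / ``#coordinates=0-based-half-open``
    (default when unstated: 1-based inclusive, the convention of GRCh37 gene
    annotation tables).  0-based half-open intervals are converted on read.
    """
    path = Path(path)
    declared: bool | None = None
    rows: list[tuple[str, int, int, str]] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                token = line.lstrip("#").strip().lower()
                if token.startswith("coordinates="):
                    declared = token.split("=", 1)[1].startswith("1-based")
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ParseError(f"{path}:{lineno}: expected chrom, start, end, gene")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinate") from exc
            rows.append((fields[0], start, end, fields[3].strip()))
    use_one_based = one_based if one_based is not None else (
        declared if declared is not None else True
    )
    out: dict[str, list[GeneInterval]] = {}
    for chrom, start, end, gene in rows:
        if not use_one_based:
            start, end = start + 1, end  # half-open [start, end) -> 1-based inclusive
        iv = GeneInterval(gene_symbol=gene, chrom=normalize_chrom(chrom), start=start, end=end)
        out.setdefault(gene.upper(), []).append(iv)
    return out


def write_gene_intervals(
    intervals: Mapping[str, list[GeneInterval]], path: str | Path
) -> None:
    with Path(path).open("w") as fh:
        fh.write("#coordinates=1-based-inclusive\n")
        for ivs in intervals.values():
            for iv in ivs:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.gene_symbol}\n")


def load_builtin_pathways() -> dict[str, tuple[str, frozenset[str]]]:
    """The shipped 11-pathway GMT fixture (synthetic gene membership)."""
    ref = resources.files("pathprs.data") / "antihypertensive_pathways.synthetic.gmt"
    with resources.as_file(ref) as p:
        return read_gmt(p)


def map_snps(
    variants: pd.DataFrame,
    pathway_set: PathwaySet,
    flank_bp: int = 0,
) -> dict[str, np.ndarray]:
    """Assign SNPs to pathways by genomic coordinates.

    A SNP maps to a pathway iff its position lies within
    ``[start - flank, end + flank]`` of any member gene interval on the same
    (normalized) chromosome, where ``flank = flank_bp + interval.flank_bp``.
    Returns pathway id -> strictly increasing array of row indices into
    ``variants``; the ``"combined"`` key holds the deduplicated union.
    Genes without intervals are logged and skipped.  Raises ``ValueError``
    when variants and intervals share no chromosome at all (irreconcilable
    naming).
    """
    if flank_bp < 0:
        raise ValueError("flank_bp must be non-negative")
    chroms = variants["chrom"].map(normalize_chrom).to_numpy()
    pos = variants["pos"].to_numpy(dtype=np.int64)

    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for c in np.unique(chroms):
        idx = np.flatnonzero(chroms == c)
        order = idx[np.argsort(pos[idx], kind="stable")]
        by_chrom[c] = (pos[order], order)

    interval_chroms = {
        normalize_chrom(iv.chrom)
        for ivs in pathway_set.intervals.values()
        for iv in ivs
    }
    if len(variants) and pathway_set.intervals and not (interval_chroms & set(by_chrom)):
        raise ValueError(
            "no chromosome shared between variants and gene intervals after "
            f"normalization (variants: {sorted(by_chrom)}, "
            f"intervals: {sorted(interval_chroms)})"
        )

    missing: set[str] = set()
    out: dict[str, np.ndarray] = {}
    combined: set[int] = set()
    for pid in pathway_set.pathway_ids:
        hits: set[int] = set()
        for gene in pathway_set.genes(pid):
            ivs = pathway_set.intervals_for(gene)
            if not ivs:
                missing.add(gene)
                continue
            for iv in ivs:
                c = normalize_chrom(iv.chrom)
                if c not in by_chrom:
                    continue
                sorted_pos, order = by_chrom[c]
                pad = flank_bp + iv.flank_bp
                lo = np.searchsorted(sorted_pos, iv.start - pad, side="left")
                hi = np.searchsorted(sorted_pos, iv.end + pad, side="right")
                hits.update(order[lo:hi].tolist())
        out[pid] = np.array(sorted(hits), dtype=np.intp)
        combined |= hits
    out[COMBINED] = np.array(sorted(combined), dtype=np.intp)
    if missing:
        logger.warning(
            "map_snps: %d gene symbol(s) without intervals skipped (e.g. %s)",
            len(missing), sorted(missing)[:5],
        )
    return out


def snp_map_to_frame(
    snp_map: Mapping[str, np.ndarray], variants: pd.DataFrame
) -> pd.DataFrame:
    """Long-format view of a SNP-pathway map (pathway_id, snp_id)."""
    recs = [
        (pid, variants["snp_id"].iat[i])
        for pid, idx in snp_map.items()
        for i in idx
    ]
    return pd.DataFrame(recs, columns=["pathway_id", "snp_id"])
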