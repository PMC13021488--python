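"""Map the simulated SNPs to the eleven antihypertensive-target pathways.

Reports per-pathway SNP and gene counts and the size of the combined
(union) set, mirroring the pathway-registry bookkeeping of the study
design.  Reads the annotation written by ``01_simulate_cohorts.py`` when
present, otherwise regenerates it from the shared configuration.
"""

import pandas as pd

from common import RESULTS, SCRATCH, STUDY_CONFIG
from pathprs.pathways import (
    PathwaySet,
    map_snps,
    read_gene_intervals,
    read_gmt,
    snp_map_to_frame,
)
from pathprs.synthdata import simulate_annotation, simulate_genotypes


def main() -> None:
    RESULTS.mkdir(parents=True, exist_ok=True)
    gmt = SCRATCH / "pathways.gmt"
    if gmt.exists():
        pathway_set = PathwaySet(
            pathways=read_gmt(gmt),
            intervals=read_gene_intervals(SCRATCH / "gene_intervals.tsv"),
        )
    else:
        pathway_set = simulate_annotation(STUDY_CONFIG)
    _, variants, _ = simulate_genotypes(STUDY_CONFIG, 2)

    snp_map = map_snps(variants, pathway_set)
    rows = []
    for pid in [*pathway_set.pathway_ids, "combined"]:
        genes = (
            pathway_set.combined_genes if pid == "combined" else pathway_set.genes(pid)
        )
        rows.append(
            {"pathway_id": pid, "n_genes": len(genes), "n_snps": len(snp_map[pid])}
        )
    table = pd.DataFrame(rows)
    table.to_csv(RESULTS / "pathway_snp_counts.tsv", sep="\t", index=False)
    snp_map_to_frame(snp_map, variants).to_csv(
        RESULTS / "snp_pathway_map.tsv", sep="\t", index=False
    )
    print(table.to_string(index=False))
    combined = table.loc[table.pathway_id == "combined"].iloc[0]
    print(
        f"\nunion across the 11 pathways: {combined.n_genes} unique genes, "
        f"{combined.n_snps} SNPs"
    )


if __name__ == "__main__":
    main()
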