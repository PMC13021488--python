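"""LD clumping (validation cohort as reference) and threshold selection.

Clumps each trait's discovery associations with the 250 kb / r² > 0.1 rule
using EM haplotype-frequency r² estimated in the validation cohort, then
scans the seven p-value thresholds for the combined-pathway PRS on the
validation cohort and reports the selected threshold per trait.
"""

import pandas as pd

from common import RESULTS, STUDY_CONFIG
from pathprs.assoc import TRAITS, gwas_additive, trait_column
from pathprs.ldclump import LdParams, clumped_to_frame, greedy_clump
from pathprs.pathways import map_snps
from pathprs.pipeline import prepare_cohort
from pathprs.score import THRESHOLD_GRID, build_model, scan_thresholds
from pathprs.synthdata import simulate_annotation, simulate_cohort, true_effects


def main() -> None:
    RESULTS.mkdir(parents=True, exist_ok=True)
    pathway_set = simulate_annotation(STUDY_CONFIG)
    betas = true_effects(STUDY_CONFIG, pathway_set)
    disc = prepare_cohort(simulate_cohort(STUDY_CONFIG, "discovery", pathway_set, betas))
    valid = prepare_cohort(
        simulate_cohort(STUDY_CONFIG, "validation", pathway_set, betas)
    )
    snp_map = map_snps(disc.variants, pathway_set)
    params = LdParams()  # 250 kb window, r² 0.1, validation reference

    cache: dict = {}
    rows = []
    for trait in TRAITS:
        assoc = gwas_additive(
            disc.dosages, disc.phenotypes[trait_column(trait)],
            disc.covariates, disc.variants,
        )
        clumped = greedy_clump(
            assoc, valid.dosages, valid.variants, params=params, r2_cache=cache
        )
        clumped_to_frame(clumped).to_csv(
            RESULTS / f"clump_{trait}.tsv", sep="\t", index=False
        )
        models = {
            thr: build_model(
                assoc, clumped, snp_map, disc.variants, trait, "combined", thr
            )
            for thr in THRESHOLD_GRID
        }
        scan, selected = scan_thresholds(
            models, valid.dosages, valid.variants,
            valid.phenotypes[trait_column(trait)], valid.covariates,
            allele_freqs=valid.allele_freqs,
        )
        scan.to_csv(RESULTS / f"scan_combined_{trait}.tsv", sep="\t", index=False)
        rows.append(
            {
                "trait": trait,
                "n_index_snps": len(clumped.index_snps),
                "selected_threshold": selected,
                "n_snps_at_selected": models[selected].n_snps,
                "validation_r2_increment": float(
                    scan.loc[scan.threshold == selected, "r2_increment"].iloc[0]
                ),
            }
        )
    table = pd.DataFrame(rows)
    table.to_csv(RESULTS / "threshold_selection.tsv", sep="\t", index=False)
    print(table.to_string(index=False))


if __name__ == "__main__":
    main()
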