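"""Shared study configuration for the numbered analysis scripts.

Cohort sizes follow the three-cohort design (discovery 2,295 / validation
1,614 / target 966); 1,200 SNPs in 60 LD blocks; blood-pressure signal at
h² = 0.15 concentrated in the cAMP signaling pathway (hsa04024).
"""

from pathlib import Path

from pathprs.synthdata import SimConfig

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results" / "analysis"
SCRATCH = ROOT / "scratch" / "cohorts"

STUDY_CONFIG = SimConfig(
    causal_pathways=("hsa04024",),
    h2_per_trait={"sbp": 0.15, "dbp": 0.15},
    seed=2026,
)
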