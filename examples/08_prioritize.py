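"""Concordance triage of differentially expressed genes against disease
genetics: orient eQTL Z-scores to the risk allele and compare with the
DEG direction.

The two hand-built cases below mirror the canonical patterns: a single
risk allele lowering expression of a down-regulated DEG (concordant), and
two independent signals with opposite effects (mixed).
"""

import pandas as pd

from isletdeck.prioritize import prioritize_genes

gwas = pd.DataFrame(
    [
        {"variant_id": "rsA", "risk_allele": "A", "other_allele": "G",
         "odds_ratio": 1.07, "p": 1.7e-68, "study": "meta", "locus": "L1"},
        {"variant_id": "rsB", "risk_allele": "A", "other_allele": "G",
         "odds_ratio": 1.03, "p": 2.1e-18, "study": "meta", "locus": "L2"},
        {"variant_id": "rsC", "risk_allele": "T", "other_allele": "C",
         "odds_ratio": 1.04, "p": 2.2e-15, "study": "meta", "locus": "L3"},
    ]
)
ld = pd.DataFrame([{"v1": "rsB", "v2": "rsC", "r2": 0.28, "phase_risk_allele": ""}])
eqtl = pd.DataFrame(
    [
        {"variant_id": "rsA", "effect_allele": "A", "gene": "DOWN_GENE",
         "z": -2.02, "p": 0.04, "cohort_directions": "----"},
        {"variant_id": "rsB", "effect_allele": "A", "gene": "SPLIT_GENE",
         "z": 2.1, "p": 0.04, "cohort_directions": "++++"},
        {"variant_id": "rsC", "effect_allele": "T", "gene": "SPLIT_GENE",
         "z": -2.18, "p": 0.03, "cohort_directions": "----"},
    ]
)
degs = pd.DataFrame(
    [
        {"gene": "DOWN_GENE", "log2fc": -1.36, "fdr": 8.5e-4},
        {"gene": "SPLIT_GENE", "log2fc": -0.72, "fdr": 0.004},
    ]
)
mouse = pd.DataFrame(
    [{"gene": "DOWN_GENE", "phenotype": "glucose tolerance", "direction": "impaired"}]
)

table = prioritize_genes(gwas, ld, eqtl, degs, mouse_ko=mouse)
print(table[["gene", "class", "n_signals", "deg_log2fc",
             "mouse_ko_direction_match", "candidate"]].to_string(index=False))
# DOWN_GENE: concordant candidate with mouse support; SPLIT_GENE: mixed
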