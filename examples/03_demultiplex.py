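"""Assign pooled droplets to donors from genotype-discriminating variants.

Each droplet's base calls are scored under every singlet and donor-pair
mixture; a doublet call needs a 2-nat margin over the best singlet.
"""

from isletdeck import demux as dx
from isletdeck.synthetic import SimulationConfig, simulate_cohort

cohort = simulate_cohort(
    SimulationConfig(seed=11, n_donors=(1, 0, 1), cells_per_donor=250,
                     n_genes=400, n_empty_droplets=400, n_variants=100)
)
cells, best = dx.demux_library(
    cohort.bundle.cells, "L00", cohort.pileups, cohort.genotypes,
    cohort.bundle.multiplex_map,
)
print(best["type"].value_counts().to_dict())

truth = cohort.truth.droplets.set_index(["library_id", "barcode_id"])
n = ok = 0
for _, row in best.iterrows():
    tr = truth.loc[("L00", row["barcode_id"])]
    if tr["kind"] == "cell":
        n += 1
        ok += row["type"] == "singlet" and row["donors"] == tr["donor_id"]
print(f"singlet accuracy vs ground truth: {ok}/{n} = {ok / n:.4f}")
# with 100 variants at 1 % call error the assignment is essentially perfect
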