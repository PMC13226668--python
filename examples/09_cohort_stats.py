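"""Cohort-level statistics: state attribute similarity, beta-cell loss across
glycemic states, and composition-HbA1c correlation."""

from isletdeck import cohort_stats as cs
from isletdeck._stats import spearman, tukey_hsd
from isletdeck.synthetic import simulate_composition_cohort, simulate_donor_metadata, SimulationConfig

# donor demographics and the cosine similarity of state attribute vectors
donors = simulate_donor_metadata(SimulationConfig(seed=2, n_donors=(17, 14, 17)))
import pandas as pd

donor_df = pd.DataFrame(
    [{"donor_id": d.donor_id, "state": d.state.value, "hba1c": d.hba1c,
      "age": d.age, "bmi": d.bmi, "sex": d.sex, "ancestry": d.ancestry} for d in donors]
)
print("state similarity (cosine of sex/ancestry/age/BMI encodings):")
print(cs.state_similarity_matrix(donor_df).round(3))
print("\nGames-Howell on HbA1c across states:")
print(cs.demographics_games_howell(donor_df, "hba1c").round(4).to_string(index=False))

# composition: beta-cell percentage by state and its HbA1c correlation
comp = simulate_composition_cohort({"ND": 17, "T2D": 17}, seed=2)
groups = {s: comp[comp["state"] == s]["beta_pct"].to_numpy() for s in ("ND", "T2D")}
print(f"\nbeta %: ND mean {groups['ND'].mean():.1f}, T2D mean {groups['T2D'].mean():.1f}")
print(f"Tukey p for the T2D reduction: {tukey_hsd(groups)[0].p:.4f}")
rho, p = spearman(comp["beta_pct"].to_numpy(), comp["hba1c"].to_numpy())
print(f"Spearman rho(beta %, HbA1c) = {rho:.2f} (p = {p:.3g}) — negative, as expected")
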