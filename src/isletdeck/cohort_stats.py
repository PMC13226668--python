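"""Cohort-level descriptive statistics.

Glycemic-state attribute similarity (cosine over encoded sex/ancestry/age/
BMI vectors), per-cell-type composition comparisons across states (ANOVA +
Tukey HSD with Bonferroni across cell types), composition-trait Spearman
correlations, and the Games-Howell post-hoc test for donor demographics.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._stats import anova_tukey_table, games_howell, spearman


def state_similarity(a: np.ndarray, b: np.ndarray) -> float:
    """Cosine similarity S(a, b) = sum a_i b_i / (||a|| ||b||)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("attribute vectors must be non-zero")
    return float(np.dot(a, b) / (na * nb))


def encode_state_attributes(donors: pd.DataFrame) -> pd.DataFrame:
    """Per-state 4-vectors: fraction female, fraction majority ancestry,
    min-max scaled mean age, min-max scaled mean BMI.

    The encoding is a declared convention (configurable upstream); the
    similarity itself is the plain cosine.
    """
    majority = donors["ancestry"].mode().iloc[0]
    rows = {}
    for state, grp in donors.groupby("state"):
        rows[state] = {
            "frac_female": (grp["sex"] == "F").mean(),
            "frac_majority_ancestry": (grp["ancestry"] == majority).mean(),
            "mean_age": grp["age"].astype(float).mean(),
            "mean_bmi": grp["bmi"].astype(float).mean(),
        }
    enc = pd.DataFrame(rows).T
    for col in ("mean_age", "mean_bmi"):
        lo, hi = enc[col].min(), enc[col].max()
        enc[col] = (enc[col] - lo) / (hi - lo) if hi > lo else 1.0
    return enc


def state_similarity_matrix(donors: pd.DataFrame) -> pd.DataFrame:
    enc = encode_state_attributes(donors)
    states = list(enc.index)
    out = pd.DataFrame(np.eye(len(states)), index=states, columns=states)
    for i, a in enumerate(states):
        for j, b in enumerate(states):
            if i < j:
                s = state_similarity(enc.loc[a].to_numpy(), enc.loc[b].to_numpy())
                out.loc[a, b] = out.loc[b, a] = s
    return out


def composition_table(
    cells: pd.DataFrame,
    donors: pd.DataFrame,
    endocrine_types: Sequence[str] = ("beta", "alpha", "delta", "gamma"),
    exclude_rare: Sequence[str] = ("epsilon",),
) -> pd.DataFrame:
    """Per-donor cell-type percentages under overall and endocrine denominators."""
    kept = cells[(~cells["filtered"]) & cells["cell_type"].notna() & cells["donor_id"].notna()]
    state_map = donors.set_index("donor_id")["state"]
    rows = []
    for donor, grp in kept.groupby("donor_id"):
        total = len(grp)
        endo = grp[grp["cell_type"].isin(endocrine_types)]
        n_endo = len(endo)
        for ct in sorted(kept["cell_type"].unique()):
            if ct in exclude_rare:
                continue
            n = (grp["cell_type"] == ct).sum()
            rows.append(
                {
                    "donor_id": donor,
                    "state": state_map.get(donor),
                    "cell_type": ct,
                    "pct_overall": 100.0 * n / total if total else np.nan,
                    "pct_endocrine": (
                        100.0 * n / n_endo if ct in endocrine_types and n_endo else np.nan
                    ),
                }
            )
    return pd.DataFrame(rows)


def composition_tests(
    ct: pd.DataFrame, value_col: str = "pct_endocrine"
) -> pd.DataFrame:
    """Per cell type, one-way ANOVA across states plus Tukey HSD pairs.

    Bonferroni correction is applied across the tested cell types.
    """
    types = [
        t
        for t, grp in ct.dropna(subset=[value_col]).groupby("cell_type")
        if grp.groupby("state")["donor_id"].nunique().ge(2).sum() >= 2
    ]
    m = len(types)
    rows = []
    for t in types:
        sub = ct[(ct["cell_type"] == t)].dropna(subset=[value_col])
        sizes = sub.groupby("state")["donor_id"].nunique()
        sub = sub[sub["state"].isin(sizes[sizes >= 2].index)]
        f, p, pairs = anova_tukey_table(sub[value_col], sub["state"], bonferroni_m=m)
        for _, r in pairs.iterrows():
            rows.append(
                {
                    "cell_type": t,
                    "anova_F": f,
                    "anova_p": p,
                    **r.to_dict(),
                    "significant": r["p_adj"] <= 0.05,
                    "direction": "higher" if r["diff"] > 0 else "lower",
                }
            )
    return pd.DataFrame(rows)


def composition_trait_correlation(
    ct: pd.DataFrame, trait: pd.Series, value_col: str = "pct_endocrine"
) -> pd.DataFrame:
    """Spearman rho between each cell type's per-donor percentage and a donor trait."""
    rows = []
    for t, grp in ct.dropna(subset=[value_col]).groupby("cell_type"):
        merged = grp.set_index("donor_id")[value_col]
        common = merged.index.intersection(trait.index)
        if len(common) < 3:
            continue
        rho, p = spearman(merged.loc[common].to_numpy(), trait.loc[common].to_numpy())
        rows.append({"cell_type": t, "rho": rho, "p": p,
                     "sign": "negative" if rho < 0 else "positive"})
    return pd.DataFrame(rows)


def demographics_games_howell(donors: pd.DataFrame, column: str) -> pd.DataFrame:
    """Games-Howell pairwise comparison of a donor attribute across states."""
    groups: Mapping[str, np.ndarray] = {
        str(s): grp[column].astype(float).to_numpy() for s, grp in donors.groupby("state")
    }
    res = games_howell(groups)
    return pd.DataFrame(
        [{"group_a": r.group_a, "group_b": r.group_b, "diff": r.diff, "p": r.p,
          "significant": r.p < 0.05} for r in res]
    )
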