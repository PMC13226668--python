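"""Candidate causal gene triage from GWAS, LD, eQTL, proteomic and mouse-KO evidence.

Index disease-risk variants are expanded with LD proxies (r^2 >= 0.80,
single hop), islet eQTL records are filtered to p < 0.05 with a consistent
direction string across all four cohorts (++++ or ----), each retained
signal's Z is oriented to the risk allele, and genes are classified
concordant / discordant / mixed by comparing oriented eQTL signs with the
differential-expression sign.  Orthogonal protein fold-change and mouse
knockout glycemic phenotypes are folded in as evidence flags.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd


def expand_ld_proxies(
    index_variants: pd.DataFrame,
    ld_pairs: pd.DataFrame,
    r2_min: float = 0.80,
) -> pd.DataFrame:
    """Single-hop closure of the index set under LD pairs at r^2 >= r2_min.

    ``index_variants`` columns: variant_id, risk_allele, other_allele, locus
    (extra columns pass through).  ``ld_pairs`` columns: v1, v2, r2 and an
    optional phase_risk_allele column giving the proxy allele in phase with
    the index risk allele; proxies without phase are flagged
    orientation_unknown.  Each proxy inherits its index's locus.
    """
    out = index_variants.copy()
    out["is_proxy"] = False
    out["index_variant"] = out["variant_id"]
    out["orientation_unknown"] = False
    if len(ld_pairs) == 0:
        return out
    sym = pd.concat(
        [
            ld_pairs.rename(columns={"v1": "a", "v2": "b"}),
            ld_pairs.rename(columns={"v1": "b", "v2": "a"}),
        ],
        ignore_index=True,
    )
    sym = sym[sym["r2"] >= r2_min]
    rows = []
    known = set(out["variant_id"])
    for _, iv in index_variants.iterrows():
        hits = sym[sym["a"] == iv["variant_id"]]
        for _, h in hits.iterrows():
            if h["b"] in known:
                continue
            phase = h.get("phase_risk_allele", "")
            has_phase = isinstance(phase, str) and phase != ""
            rows.append(
                {
                    "variant_id": h["b"],
                    "risk_allele": phase if has_phase else "",
                    "other_allele": "",
                    "locus": iv.get("locus", iv["variant_id"]),
                    "odds_ratio": iv.get("odds_ratio", np.nan),
                    "p": iv.get("p", np.nan),
                    "study": iv.get("study", ""),
                    "is_proxy": True,
                    "index_variant": iv["variant_id"],
                    "orientation_unknown": not has_phase,
                }
            )
            known.add(h["b"])
    return pd.concat([out, pd.DataFrame(rows)], ignore_index=True) if rows else out


def filter_eqtls(
    records: pd.DataFrame, p_max: float = 0.05, require_consistent: bool = True
) -> pd.DataFrame:
    """Keep eQTLs with p < p_max and direction string ++++ or ---- (when required)."""
    dirs = records["cohort_directions"].astype(str)
    bad = ~dirs.str.fullmatch(r"[+-]{4}")
    if bad.any():
        row = records.index[bad][0]
        raise ValueError(f"malformed cohort_directions at row {row}: {dirs.loc[row]!r}")
    keep = records["p"] < p_max
    if require_consistent:
        keep &= dirs.isin(["++++", "----"])
    return records[keep].reset_index(drop=True)


@dataclass
class ConcordanceCall:
    gene: str
    klass: str  # concordant | discordant | mixed
    supporting_variants: tuple[str, ...]
    deg_log2fc: float
    protein_direction_match: bool = False
    mouse_ko_direction_match: bool = False
    candidate: bool = False


def classify_concordance(
    variants: pd.DataFrame,
    eqtls: pd.DataFrame,
    degs: pd.DataFrame,
) -> pd.DataFrame:
    """Per-gene concordance class from risk-allele-oriented eQTL signs.

    ``variants``: expanded variant table (risk_allele, locus,
    orientation_unknown).  ``eqtls``: retained records (variant_id,
    effect_allele, gene, z).  ``degs``: gene -> log2fc (+ optional fdr).
    Signals from the same locus collapse to the max-|z| record; a gene is
    concordant if all its oriented signals match the DEG sign, discordant if
    none do, mixed otherwise.  Oriented z of exactly 0 is uninformative and
    excluded; orientation-unknown proxies are excluded rather than guessed.
    """
    vinfo = variants.set_index("variant_id")
    deg_map = degs.set_index("gene")["log2fc"]
    rows = []
    merged = eqtls[eqtls["variant_id"].isin(vinfo.index)].copy()
    for gene, grp in merged.groupby("gene"):
        if gene not in deg_map.index:
            continue
        deg_sign = int(np.sign(deg_map.loc[gene]))
        signals = {}
        for _, r in grp.iterrows():
            v = vinfo.loc[r["variant_id"]]
            if bool(v.get("orientation_unknown", False)):
                continue
            risk = v["risk_allele"]
            z = float(r["z"])
            oriented = z if r["effect_allele"] == risk else -z
            if oriented == 0:
                continue
            locus = v.get("locus", r["variant_id"])
            if locus not in signals or abs(oriented) > abs(signals[locus][1]):
                signals[locus] = (r["variant_id"], oriented)
        if not signals:
            continue
        signs = [int(np.sign(z)) for _, z in signals.values()]
        matches = [s == deg_sign for s in signs]
        if all(matches):
            klass = "concordant"
        elif not any(matches):
            klass = "discordant"
        else:
            klass = "mixed"
        rows.append(
            {
                "gene": gene,
                "class": klass,
                "supporting_variants": tuple(v for v, _ in signals.values()),
                "n_signals": len(signals),
                "deg_log2fc": float(deg_map.loc[gene]),
                "deg_fdr": float(degs.set_index("gene").get("fdr", pd.Series(dtype=float)).get(gene, np.nan)),
            }
        )
    return pd.DataFrame(rows)


def integrate_evidence(
    calls: pd.DataFrame,
    protein_table: Optional[pd.DataFrame] = None,
    mouse_table: Optional[pd.DataFrame] = None,
    protein_p_max: float = 0.05,
) -> pd.DataFrame:
    """Fold protein and mouse-KO direction evidence into the candidate table.

    protein flag: protein fold-change sign matches the DEG sign at
    p <= protein_p_max.  mouse flag: knockout phenotype direction is
    disease-consistent for the DEG direction (down-DEG + impaired glucose
    tolerance, or up-DEG + improved).  candidate = concordant class OR >= 1
    orthogonal flag; ranked by (class, #flags, DEG FDR).
    """
    out = calls.copy()
    prot = (
        protein_table.set_index("gene")
        if protein_table is not None and len(protein_table)
        else pd.DataFrame()
    )
    mouse = (
        mouse_table.set_index("gene")
        if mouse_table is not None and len(mouse_table)
        else pd.DataFrame()
    )
    p_flags, m_flags = [], []
    for _, r in out.iterrows():
        g = r["gene"]
        deg_sign = int(np.sign(r["deg_log2fc"]))
        pf = False
        if g in prot.index:
            pr = prot.loc[g]
            pf = (
                float(pr.get("p", 1.0)) <= protein_p_max
                and int(np.sign(float(pr["log2fc"]))) == deg_sign
            )
        mf = False
        if g in mouse.index:
            mr = mouse.loc[g]
            direction = str(mr["direction"]).lower()
            mf = (deg_sign < 0 and direction == "impaired") or (
                deg_sign > 0 and direction == "improved"
            )
        p_flags.append(bool(pf))
        m_flags.append(bool(mf))
    out["protein_direction_match"] = p_flags
    out["mouse_ko_direction_match"] = m_flags
    out["n_flags"] = out["protein_direction_match"].astype(int) + out[
        "mouse_ko_direction_match"
    ].astype(int)
    out["candidate"] = (out["class"] == "concordant") | (out["n_flags"] >= 1)
    class_rank = {"concordant": 0, "mixed": 1, "discordant": 2}
    out["_cr"] = out["class"].map(class_rank)
    out = out.sort_values(
        ["_cr", "n_flags", "deg_fdr"], ascending=[True, False, True]
    ).drop(columns="_cr").reset_index(drop=True)
    return out


def prioritize_genes(
    gwas: pd.DataFrame,
    ld: pd.DataFrame,
    eqtl: pd.DataFrame,
    degs: pd.DataFrame,
    protein: Optional[pd.DataFrame] = None,
    mouse_ko: Optional[pd.DataFrame] = None,
    r2_min: float = 0.80,
    eqtl_p_max: float = 0.05,
) -> pd.DataFrame:
    """Full triage: LD expansion -> eQTL filtering -> classification -> evidence."""
    expanded = expand_ld_proxies(gwas, ld, r2_min=r2_min)
    retained = filter_eqtls(eqtl, p_max=eqtl_p_max)
    calls = classify_concordance(expanded, retained, degs)
    if len(calls) == 0:
        return calls
    return integrate_evidence(calls, protein, mouse_ko)
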