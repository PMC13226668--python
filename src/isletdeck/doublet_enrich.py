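"""Cluster-level doublet enrichment.

For each cluster x the 2x2 table (doublets/singlets, inside/outside) yields
the doublet ratios DR_in = d_in/s_in and DR_out = d_out/s_out, their odds
ratio, and a two-sided Fisher exact p; clusters with OR > 2 at
Benjamini-Hochberg FDR <= 1 % are enriched.  Removal additionally requires
multi-hormone co-expression evidence by default, and also drops all residual
consensus-scorer doublets.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact

from ._stats import bh_fdr
from .cluster import HORMONE_GENES, NormalizedMatrix
from .io_cohort import flag_cells


def doublet_enrichment_test(
    labels: np.ndarray,
    doublet_flags: np.ndarray,
    or_min: float = 2.0,
    fdr_max: float = 0.01,
) -> pd.DataFrame:
    """Per-cluster doublet-enrichment rows (counts, DRs, OR, Fisher p, FDR).

    The odds ratio uses the Haldane-Anscombe 0.5 correction when any table
    cell is zero; the exact p-value is computed on the raw table.
    """
    labels = np.asarray(labels)
    doublet_flags = np.asarray(doublet_flags, dtype=bool)
    clusters = np.unique(labels)
    if len(clusters) < 2:
        raise ValueError("need at least two clusters (no complement otherwise)")
    total_d = int(doublet_flags.sum())
    total_s = int((~doublet_flags).sum())
    rows = []
    for cl in clusters:
        inside = labels == cl
        d_in = int((doublet_flags & inside).sum())
        s_in = int((~doublet_flags & inside).sum())
        d_out = total_d - d_in
        s_out = total_s - s_in
        table = np.array([[d_in, d_out], [s_in, s_out]])
        if (table == 0).any():
            t = table + 0.5
        else:
            t = table.astype(float)
        odds = (t[0, 0] / t[1, 0]) / (t[0, 1] / t[1, 1])
        _, p = fisher_exact(table, alternative="two-sided")
        dr_in = d_in / s_in if s_in else np.inf
        dr_out = d_out / s_out if s_out else np.inf
        rows.append(
            {"cluster": cl, "d_in": d_in, "s_in": s_in, "d_out": d_out, "s_out": s_out,
             "DR_in": dr_in, "DR_out": dr_out, "OR": float(odds), "p": float(p)}
        )
    out = pd.DataFrame(rows)
    out["fdr"] = bh_fdr(out["p"].to_numpy())
    out["enriched"] = (out["OR"] > or_min) & (out["fdr"] <= fdr_max)
    return out


def hormone_coexpression_flags(
    nm: NormalizedMatrix,
    labels: np.ndarray,
    hormone_genes: Sequence[str] = HORMONE_GENES,
    z_min: float = 1.0,
) -> pd.DataFrame:
    """Flag clusters whose cluster-mean z-scores exceed z_min for >= 2 hormones."""
    genes = [g for g in hormone_genes if g in nm.gene_ids]
    gi = [nm.gene_ids.index(g) for g in genes]
    dense = np.asarray(nm.values[gi, :].todense())
    clusters = np.unique(labels)
    means = np.array([dense[:, labels == cl].mean(axis=1) for cl in clusters])
    mu, sd = means.mean(axis=0), means.std(axis=0)
    sd[sd == 0] = 1.0
    z = (means - mu) / sd
    n_high = (z > z_min).sum(axis=1)
    return pd.DataFrame(
        {"cluster": clusters, "n_hormones_high": n_high, "multi_hormone": n_high >= 2}
    )


def remove_enriched_clusters(
    cells: pd.DataFrame,
    labels: np.ndarray,
    enrichment: pd.DataFrame,
    coexpr: pd.DataFrame,
    consensus_doublets: np.ndarray | None = None,
    require_both: bool = True,
) -> tuple[pd.DataFrame, list]:
    """Drop clusters that are doublet-enriched (and hormone-flagged when required).

    All member cells get reason "enriched_doublet_cluster"; residual
    consensus-scorer doublets get reason "consensus_doublet".  Returns the
    updated cell table and the list of removed clusters.
    """
    flagged = set(coexpr.loc[coexpr["multi_hormone"], "cluster"])
    removed = []
    for _, row in enrichment.iterrows():
        if not row["enriched"]:
            continue
        if require_both and row["cluster"] not in flagged:
            continue
        removed.append(row["cluster"])
    mask = np.isin(labels, removed)
    out = flag_cells(cells, mask, "enriched_doublet_cluster")
    if consensus_doublets is not None:
        out = flag_cells(out, np.asarray(consensus_doublets, dtype=bool), "consensus_doublet")
        out.loc[np.asarray(consensus_doublets, dtype=bool), "doublet"] = True
    return out, removed
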