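"""Ambient-RNA ("soup") decontamination.

The soup profile b_g is the pooled gene frequency over empty droplets
(total UMIs strictly below a threshold, default 10).  Per-cell contamination
fractions rho_c are estimated at the cluster level from genes that are
plausibly unexpressed within the cluster; expected soup counts
N_c * rho_c * b_g are then subtracted from the observed counts.
Assessment metrics (per-gene mean UMI decrease M_g, mean abundance A_g and
mean contamination rank r_g across libraries) quantify what was removed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import rankdata

from .io_cohort import CountsMatrix, FloatMatrix


@dataclass
class SoupProfile:
    b: np.ndarray  # per-gene background fraction, sums to 1
    empty_threshold: int
    n_empty: int
    gene_ids: list[str]

    def __post_init__(self) -> None:
        if self.n_empty < 1:
            raise ValueError("need at least one empty droplet")
        if (self.b < 0).any() or abs(self.b.sum() - 1.0) > 1e-12:
            raise ValueError("soup profile must be a probability simplex")


@dataclass
class ContaminationEstimate:
    rho: np.ndarray  # per-cell fraction in [0, 1]
    method: str  # "unexpressed_gene" | "fixed"
    cluster_rho: dict[object, float]

    def __post_init__(self) -> None:
        if ((self.rho < 0) | (self.rho > 1)).any():
            raise ValueError("rho must lie in [0, 1]")


@dataclass
class DecontamAssessment:
    table: pd.DataFrame  # gene, M, A, mean_rank


def estimate_soup_profile(raw: CountsMatrix, empty_threshold: int = 10) -> SoupProfile:
    """b_g = pooled counts of gene g over droplets with total < threshold."""
    totals = raw.column_totals()
    empty = totals < empty_threshold
    n_empty = int(empty.sum())
    if n_empty == 0:
        raise ValueError(
            f"no droplets with total UMIs < {empty_threshold}; "
            "raise empty_threshold or supply the raw (unfiltered) matrix"
        )
    pooled = np.asarray(raw.values[:, np.flatnonzero(empty)].sum(axis=1)).ravel().astype(float)
    if pooled.sum() == 0:
        raise ValueError("empty droplets contain zero UMIs; cannot form a soup profile")
    b = pooled / pooled.sum()
    return SoupProfile(b=b, empty_threshold=empty_threshold, n_empty=n_empty, gene_ids=list(raw.gene_ids))


def estimate_contamination(
    filtered: CountsMatrix,
    soup: SoupProfile,
    clusters: Sequence,
    method: str = "unexpressed_gene",
    fixed_rho: Optional[float] = None,
    bottom_decile: float = 0.10,
    share_cap: float = 0.50,
    anchor_mass: float = 0.003,
    gene_sets: Optional[dict] = None,
) -> ContaminationEstimate:
    """Cluster-level contamination fraction from plausibly-unexpressed genes.

    For each cluster x a set S_x of genes is selected whose within-cluster
    count share is smallest relative to the soup fraction b_g (bottom decile
    of the share/b ratio, and share below ``share_cap`` * b_g).  Counts of
    those genes inside the cluster are attributed to soup:

        rho_x = sum_{c in x, g in S_x} n_gc / (sum_{c in x} N_c * sum_{g in S_x} b_g)

    clipped to [0, 1].  Every cell inherits its cluster's estimate.  With
    ``method="fixed"`` all cells receive ``fixed_rho``.  ``gene_sets`` maps a
    cluster label to an explicit array of gene indices, bypassing selection
    (useful when the unexpressed set is known).
    """
    clusters = np.asarray(clusters)
    if len(clusters) != filtered.n_droplets:
        raise ValueError("every cell must carry a cluster label")
    if method == "fixed":
        if fixed_rho is None:
            raise ValueError("method='fixed' requires fixed_rho")
        rho = np.full(filtered.n_droplets, float(fixed_rho))
        return ContaminationEstimate(rho=rho, method="fixed",
                                     cluster_rho={c: float(fixed_rho) for c in np.unique(clusters)})
    if method != "unexpressed_gene":
        raise ValueError(f"unknown method {method!r}")

    b = soup.b
    totals = filtered.column_totals().astype(float)
    csr = filtered.values.tocsr()
    cluster_rho: dict[object, float] = {}
    rho = np.zeros(filtered.n_droplets)
    expressed_soup = b > 0

    def select_set(share: np.ndarray, n_total: float = np.inf) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(expressed_soup, share / np.where(b > 0, b, 1.0), np.inf)
        candidates = expressed_soup & (share < share_cap * b)
        if not candidates.any():
            return np.array([], dtype=int)
        order = np.argsort(np.where(candidates, ratio, np.inf), kind="mergesort")
        n_keep = max(1, int(np.ceil(bottom_decile * expressed_soup.sum())))
        keep = order[:n_keep]
        keep = keep[candidates[keep]]
        if keep.size < 2:
            return keep
        # Second pass: per-gene ratios over-estimate rho one-sidedly (any
        # residual endogenous expression adds to the soup share, never
        # subtracts).  Anchor on the lowest-ratio genes that jointly carry
        # enough soup mass for a stable share estimate, then keep only genes
        # near that anchor.
        sorted_keep = keep[np.argsort(ratio[keep])]
        cum_b = np.cumsum(b[sorted_keep])
        # shallow clusters need more prefix mass for a stable anchor: require
        # n_total * prefix_mass >= ~2000 expected-depth units
        eff_mass = max(anchor_mass, 2000.0 / max(n_total, 1.0))
        n_anchor = int(np.searchsorted(cum_b, eff_mass)) + 1
        prefix = sorted_keep[: max(n_anchor, 1)]
        anchor = float(np.sum(ratio[prefix] * b[prefix]) / np.sum(b[prefix]))
        cap2 = max(1.5 * anchor, anchor + 0.01)
        refined = keep[ratio[keep] <= cap2]
        return refined if refined.size else keep

    # global fallback set from the pooled profile
    pooled_share = np.asarray(csr.sum(axis=1)).ravel() / max(totals.sum(), 1.0)
    global_set = select_set(pooled_share)

    for cl in np.unique(clusters):
        idx = np.flatnonzero(clusters == cl)
        cl_counts = np.asarray(filtered.values[:, idx].sum(axis=1)).ravel().astype(float)
        cl_total = cl_counts.sum()
        share = cl_counts / cl_total if cl_total > 0 else cl_counts
        if gene_sets is not None and cl in gene_sets:
            s_x = np.asarray(gene_sets[cl], dtype=int)
        else:
            s_x = select_set(share, n_total=cl_total)
        if s_x.size == 0:
            s_x = global_set
        if s_x.size == 0:
            cluster_rho[cl] = 0.0
            continue
        numer = cl_counts[s_x].sum()
        denom = totals[idx].sum() * b[s_x].sum()
        est = float(np.clip(numer / denom, 0.0, 1.0)) if denom > 0 else 0.0
        cluster_rho[cl] = est
        rho[idx] = est
    return ContaminationEstimate(rho=rho, method="unexpressed_gene", cluster_rho=cluster_rho)


def correct_counts(
    filtered: CountsMatrix,
    soup: SoupProfile,
    est: ContaminationEstimate,
    clip_negative: bool = True,
) -> FloatMatrix:
    """Subtract the expected soup counts: n_tilde_gc = n_gc - N_c * rho_c * b_g."""
    if len(est.rho) != filtered.n_droplets:
        raise ValueError("contamination estimate does not cover every cell")
    if len(soup.b) != filtered.n_genes:
        raise ValueError("soup profile dimension mismatch")
    dense = np.asarray(filtered.values.todense(), dtype=float)
    totals = dense.sum(axis=0)
    expected = soup.b[:, None] * (totals * est.rho)[None, :]
    corrected = dense - expected
    if clip_negative:
        corrected = np.maximum(corrected, 0.0)
    return FloatMatrix(
        values=sp.csc_matrix(corrected),
        gene_ids=list(filtered.gene_ids),
        barcode_ids=list(filtered.barcode_ids),
        library_id=filtered.library_id,
    )


def assess_decontamination(
    uncorrected: dict[str, CountsMatrix],
    corrected: dict[str, FloatMatrix],
) -> DecontamAssessment:
    """Per-gene decontamination metrics averaged over libraries.

    M_g: mean over libraries of (mean uncorrected UMI - mean corrected UMI);
    A_g: mean over libraries of (mean uncorrected + mean corrected);
    mean_rank: mean over libraries of the rank of the per-library decrease
    (rank 1 = largest decrease; ties get average rank).
    """
    libs = sorted(uncorrected)
    if sorted(corrected) != libs:
        raise ValueError("library sets of uncorrected and corrected matrices differ")
    if not libs:
        raise ValueError("need at least one library")
    gene_ids = uncorrected[libs[0]].gene_ids
    m_acc = np.zeros(len(gene_ids))
    a_acc = np.zeros(len(gene_ids))
    r_acc = np.zeros(len(gene_ids))
    for lib in libs:
        u = np.asarray(uncorrected[lib].values.mean(axis=1)).ravel()
        c = np.asarray(corrected[lib].values.mean(axis=1)).ravel()
        dec = u - c
        m_acc += dec
        a_acc += u + c
        r_acc += rankdata(-dec, method="average")
    j = len(libs)
    table = pd.DataFrame(
        {"gene": gene_ids, "M": m_acc / j, "A": a_acc / j, "mean_rank": r_acc / j}
    )
    return DecontamAssessment(table=table)
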