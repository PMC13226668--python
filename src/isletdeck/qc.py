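"""Layered per-library quality control.

Order of operations: per-droplet metrics (nFEA, nUMI, pMT), a preliminary
hard filter, two simulated-doublet scorers whose intersection forms the
consensus doublet set, an adaptive per-library nFEA cutoff that relaxes when
an exocrine cluster would be over-filtered, per-group pMT quantile tests
(ANOVA + Tukey HSD, Bonferroni across quantiles) and the final
annotation-aware pMT rule (beta cells 40 %, everything else 20 %).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from ._stats import anova_tukey_table
from .io_cohort import CountsMatrix, flag_cells


@dataclass
class QCThresholds:
    prelim_nfea: int = 500  # filter nFEA <= this
    prelim_numi: int = 1000  # filter nUMI <= this
    prelim_pmt: float = 50.0  # filter pMT >= this
    nfea_default: int = 1400
    nfea_relaxed: int = 1000
    pmt_cut: float = 40.0
    celltype_pmt: dict = field(default_factory=lambda: {"beta": 40.0, "other": 20.0})
    pN: float = 0.25  # artificial doublet proportion
    pK: float = 0.09  # neighborhood fraction
    nExp: float = 0.1  # expected doublet fraction (quantile scorer)
    nPC: int = 10
    sim_threshold: float = 0.25  # fixed score cutoff (threshold scorer)
    exocrine_enrich_frac: float = 0.50  # > this fraction below cutoff triggers relaxation

    def __post_init__(self) -> None:
        if self.nfea_relaxed >= self.nfea_default:
            raise ValueError("relaxed cutoff must be below the default")


def compute_cell_metrics(
    m: CountsMatrix, cells: pd.DataFrame, mito_gene_set: Sequence[str]
) -> pd.DataFrame:
    """Fill nUMI (column sums), nFEA (detected genes) and pMT (% mito UMIs)."""
    mito = [g for g in mito_gene_set if g in m.gene_ids]
    if not list(mito_gene_set):
        raise ValueError("mito gene set must be non-empty")
    csc = m.values.tocsc()
    numi = np.asarray(csc.sum(axis=0)).ravel()
    nfea = np.asarray((csc > 0).sum(axis=0)).ravel()
    idx = [m.gene_ids.index(g) for g in mito]
    mito_umi = np.asarray(csc[idx, :].sum(axis=0)).ravel() if idx else np.zeros_like(numi)
    with np.errstate(invalid="ignore", divide="ignore"):
        pmt = np.where(numi > 0, 100.0 * mito_umi / np.maximum(numi, 1), 0.0)
    out = cells.copy()
    bc_pos = {b: i for i, b in enumerate(m.barcode_ids)}
    sel = out["library_id"] == m.library_id
    pos = [bc_pos[b] for b in out.loc[sel, "barcode_id"]]
    out.loc[sel, "nUMI"] = numi[pos]
    out.loc[sel, "nFEA"] = nfea[pos]
    out.loc[sel, "pMT"] = pmt[pos]
    return out


def preliminary_filter(cells: pd.DataFrame, th: QCThresholds) -> pd.DataFrame:
    """First-pass cleaning: nFEA <= 500 OR nUMI <= 1000 OR pMT >= 50 %."""
    out = cells
    out = flag_cells(out, (out["nFEA"] <= th.prelim_nfea).to_numpy(), "low_nfea_prelim")
    out = flag_cells(out, (out["nUMI"] <= th.prelim_numi).to_numpy(), "low_numi_prelim")
    out = flag_cells(out, (out["pMT"] >= th.prelim_pmt).to_numpy(), "high_pmt_prelim")
    return out


@dataclass
class DoubletScores:
    scores: np.ndarray  # per observed cell, fraction of artificial neighbors
    threshold_flags: np.ndarray  # score > sim_threshold
    quantile_flags: np.ndarray  # top nExp fraction
    consensus: np.ndarray  # intersection


def simulated_doublet_scores(
    norm: np.ndarray,
    th: QCThresholds,
    seed: int = 0,
    counts: Optional[np.ndarray] = None,
    scale_factor: float = 10_000.0,
) -> DoubletScores:
    """Score droplets by their proportion of artificial-doublet neighbors.

    ``norm``: cells x genes normalized expression.  ceil(pN * C) artificial
    doublets are co-embedded with the observed cells in nPC principal
    components; each observed cell's score is the fraction of artificial
    cells among its ceil(pK * (C + C_art)) nearest Euclidean neighbors.

    When ``counts`` (cells x genes raw UMIs) is given, artificial doublets
    sum the two parents' raw counts and renormalize — matching the additive
    noise of real doublets.  Without counts they average the parents'
    normalized profiles, which understates doublet sampling noise.
    """
    c = norm.shape[0]
    if c < 20:
        raise ValueError("need at least 20 cells")
    if th.pN <= 0:
        raise ValueError("pN must be positive (no artificial doublets otherwise)")
    rng = np.random.default_rng(seed)
    n_art = int(np.ceil(th.pN * c))
    a = rng.integers(0, c, size=n_art)
    b = (a + 1 + rng.integers(0, c - 1, size=n_art)) % c  # distinct partner
    if counts is not None:
        summed = counts[a] + counts[b]
        totals = np.maximum(summed.sum(axis=1, keepdims=True), 1.0)
        art = np.log1p(scale_factor * summed / totals)
    else:
        art = (norm[a] + norm[b]) / 2.0
    stacked = np.vstack([norm, art])
    mu = stacked.mean(axis=0)
    sd = stacked.std(axis=0)
    sd[sd == 0] = 1.0
    stacked = (stacked - mu) / sd  # unit-scaled features, standard pre-PCA
    n_pcs = min(th.nPC, min(stacked.shape) - 1)
    emb = PCA(n_components=n_pcs, svd_solver="full").fit_transform(stacked)
    k = int(np.ceil(th.pK * stacked.shape[0]))
    if k >= stacked.shape[0]:
        raise ValueError("neighborhood size exceeds number of cells")
    nn = NearestNeighbors(n_neighbors=k + 1).fit(emb)
    _, idx = nn.kneighbors(emb[:c])
    idx = idx[:, 1:]  # drop self
    scores = (idx >= c).mean(axis=1)
    threshold_flags = scores > th.sim_threshold
    n_flag = int(np.ceil(th.nExp * c))
    # stable order on ties: argsort by (-score, index)
    order = np.lexsort((np.arange(c), -scores))
    quantile_flags = np.zeros(c, dtype=bool)
    quantile_flags[order[:n_flag]] = True
    return DoubletScores(scores, threshold_flags, quantile_flags, threshold_flags & quantile_flags)


def consensus_doublets(scores: DoubletScores) -> np.ndarray:
    """Consensus = intersection of the two scorers' flag sets."""
    return scores.threshold_flags & scores.quantile_flags


def adaptive_nfea_threshold(
    cells: pd.DataFrame,
    th: QCThresholds,
    exocrine_types: Sequence[str] = ("acinar", "ductal"),
) -> tuple[int, Optional[object]]:
    """Per-library nFEA cutoff; relaxed when an exocrine cluster would be gutted.

    If any cluster pre-annotated as an exocrine type has strictly more than
    ``exocrine_enrich_frac`` of its cells below the default cutoff, the
    relaxed cutoff applies.  Returns (cutoff, triggering cluster or None).
    """
    if cells["cell_type"].isna().all():
        return th.nfea_default, None
    for cl, grp in cells.groupby("cluster", dropna=True):
        ct = grp["cell_type"].mode()
        if len(ct) == 0 or ct.iloc[0] not in exocrine_types:
            continue
        frac = (grp["nFEA"] < th.nfea_default).mean()
        if frac > th.exocrine_enrich_frac:
            return th.nfea_relaxed, cl
    return th.nfea_default, None


def flag_cells_nfea(cells: pd.DataFrame, library_mask, cutoff: int) -> pd.DataFrame:
    """Flag cells of one library below the (possibly relaxed) nFEA cutoff."""
    mask = np.asarray(library_mask) & (cells["nFEA"] < cutoff).to_numpy()
    return flag_cells(cells, mask, "low_nfea")


def flag_high_pmt(cells: pd.DataFrame, th: QCThresholds) -> pd.DataFrame:
    """Library-stage mitochondrial cutoff: flag cells with pMT > pmt_cut."""
    return flag_cells(cells, (cells["pMT"] > th.pmt_cut).to_numpy(), "high_pmt")


def group_pmt_comparison(
    cells: pd.DataFrame,
    grouping: str,
    quantiles: Sequence[float] = (50, 70, 90),
) -> pd.DataFrame:
    """ANOVA + Tukey HSD on per-donor pMT quantiles, Bonferroni across quantiles.

    ``grouping`` is a cell-table column ("cell_type" or donor state merged in
    beforehand).  The unit of analysis is the per-donor quantile of pMT, so
    cells are never pseudo-replicated.  Groups with a single donor are
    excluded.
    """
    rows = []
    m = len(quantiles)
    for q in quantiles:
        per_donor = (
            cells.groupby([grouping, "donor_id"], observed=True)["pMT"]
            .quantile(q / 100.0)
            .reset_index()
        )
        sizes = per_donor.groupby(grouping, observed=True)["donor_id"].nunique()
        keep = sizes[sizes >= 2].index
        sub = per_donor[per_donor[grouping].isin(keep)]
        if sub[grouping].nunique() < 2:
            continue
        f, p, pairs = anova_tukey_table(sub["pMT"], sub[grouping], bonferroni_m=m)
        for _, r in pairs.iterrows():
            rows.append(
                {"quantile": q, "anova_F": f, "anova_p": p, **r.to_dict(),
                 "significant": r["p_adj"] <= 0.05}
            )
    return pd.DataFrame(rows)


def annotation_aware_filter(cells: pd.DataFrame, th: QCThresholds) -> pd.DataFrame:
    """Final pMT rule: beta cells dropped at pMT >= 40, other types at >= 20."""
    beta_cut = th.celltype_pmt.get("beta", 40.0)
    other_cut = th.celltype_pmt.get("other", 20.0)
    ct = cells["cell_type"].fillna("other")
    is_beta = ct == "beta"
    mask = np.where(is_beta, cells["pMT"] >= beta_cut, cells["pMT"] >= other_cut)
    return flag_cells(cells, mask, "celltype_pmt")
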