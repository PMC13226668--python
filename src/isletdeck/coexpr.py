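"""Signed weighted co-expression modules on covariate-residualized pseudobulk.

Pipeline: residualize covariates per gene (OLS, grand mean added back),
scan soft-threshold powers for scale-free topology fit, build the signed
adjacency a_ij = ((1 + cor(x_i, x_j)) / 2)^t, form the topological overlap
matrix (TOM), detect modules by average-linkage hierarchical clustering on
1 - TOM with a size filter and eigengene-based merging, and correlate
module eigengenes with traits by Spearman rank correlation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import squareform

from ._stats import spearman


@dataclass
class NetworkConfig:
    power_grid: tuple[int, ...] = tuple(range(1, 21))
    chosen_power: int = 12
    signed: bool = True
    min_module_size: int = 100
    merge_cut_height: float = 0.25
    cut_height_frac: float = 0.99  # initial tree cut at this fraction of the max join
    kme_min: float = 0.30  # genes below this eigengene correlation are pruned to grey

    def __post_init__(self) -> None:
        if self.chosen_power not in self.power_grid:
            raise ValueError("chosen_power must be in the power grid")
        if self.min_module_size < 2:
            raise ValueError("min_module_size must be >= 2")


def residualize_covariates(expr: pd.DataFrame, covariates: pd.DataFrame) -> pd.DataFrame:
    """Per-gene OLS on covariates (state excluded); residuals + gene grand mean.

    ``expr``: genes x samples; ``covariates``: samples x columns (categorical
    columns are dummy-coded).  Residuals are exactly orthogonal to every
    covariate column.
    """
    x = pd.get_dummies(covariates, drop_first=True).astype(float)
    x.insert(0, "intercept", 1.0)
    xm = x.to_numpy()
    if np.linalg.matrix_rank(xm) < xm.shape[1]:
        raise ValueError("rank-deficient covariate design")
    y = expr.to_numpy(dtype=float).T  # samples x genes
    beta, *_ = np.linalg.lstsq(xm, y, rcond=None)
    resid = y - xm @ beta
    out = resid.T + expr.to_numpy(dtype=float).mean(axis=1, keepdims=True)
    return pd.DataFrame(out, index=expr.index, columns=expr.columns)


def signed_adjacency(expr: pd.DataFrame, power: int) -> np.ndarray:
    """a_ij = ((1 + cor(x_i, x_j)) / 2)^power with zero diagonal."""
    x = expr.to_numpy(dtype=float)
    sd = x.std(axis=1)
    if (sd == 0).any():
        raise ValueError("constant gene(s) present; drop them before network construction")
    cor = np.corrcoef(x)
    a = ((1.0 + cor) / 2.0) ** power
    np.fill_diagonal(a, 0.0)
    return a


def soft_threshold_scan(
    expr: pd.DataFrame, grid: Sequence[int] = tuple(range(1, 21)), n_bins: int = 10
) -> pd.DataFrame:
    """Scale-free topology fit R^2 and mean connectivity per candidate power.

    R^2 is the fit of log10 p(k) vs log10 k over binned connectivities, with
    the sign flipped negative when the slope is positive (hub-poor networks
    should not score well).
    """
    if expr.shape[0] < 30:
        raise ValueError("need at least 30 genes for a meaningful scan")
    sd = expr.to_numpy(dtype=float).std(axis=1)
    use = expr.loc[sd > 0]
    rows = []
    for t in grid:
        a = signed_adjacency(use, t)
        k = a.sum(axis=1)
        mean_k = float(k.mean())
        # bin connectivities, regress log10 freq on log10 mean-k
        edges = np.linspace(k.min(), k.max(), n_bins + 1)
        which = np.clip(np.digitize(k, edges) - 1, 0, n_bins - 1)
        xs, ys = [], []
        for b in range(n_bins):
            mask = which == b
            if mask.sum() == 0:
                continue
            kb = k[mask].mean()
            pb = mask.mean()
            if kb > 0 and pb > 0:
                xs.append(np.log10(kb))
                ys.append(np.log10(pb))
        if len(xs) >= 3 and np.std(xs) > 0:
            slope, intercept = np.polyfit(xs, ys, 1)
            pred = np.polyval([slope, intercept], xs)
            ss_res = np.sum((np.array(ys) - pred) ** 2)
            ss_tot = np.sum((np.array(ys) - np.mean(ys)) ** 2)
            r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
            if slope > 0:
                r2 = -r2
        else:
            r2, slope = 0.0, 0.0
        rows.append({"power": t, "sft_r2": float(r2), "slope": float(slope),
                     "mean_connectivity": mean_k})
    return pd.DataFrame(rows)


def tom_similarity(adjacency: np.ndarray) -> np.ndarray:
    """TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij); TOM_ii = 1."""
    a = np.asarray(adjacency, dtype=float)
    if a.shape[0] != a.shape[1]:
        raise ValueError("adjacency must be square")
    if np.abs(a - a.T).max() > 1e-10:
        raise ValueError("adjacency must be symmetric")
    if np.abs(np.diag(a)).max() > 1e-12:
        raise ValueError("adjacency diagonal must be zero")
    l = a @ a
    k = a.sum(axis=1)
    min_k = np.minimum.outer(k, k)
    tom = (l + a) / (min_k + 1.0 - a)
    np.fill_diagonal(tom, 1.0)
    return tom


@dataclass
class ModulePartition:
    labels: np.ndarray  # per-gene module id; 0 = grey/unassigned
    gene_ids: list[str]
    eigengenes: pd.DataFrame  # modules x samples
    linkage: np.ndarray


def module_eigengene(expr: pd.DataFrame, labels: np.ndarray) -> pd.DataFrame:
    """First right singular vector of each module's standardized expression.

    Unit-norm over samples, sign-oriented to correlate positively with the
    module's mean expression profile.
    """
    out = {}
    x = expr.to_numpy(dtype=float)
    for m in sorted(set(labels) - {0}):
        sub = x[labels == m]
        mu = sub.mean(axis=1, keepdims=True)
        sd = sub.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        z = (sub - mu) / sd
        _, _, vt = np.linalg.svd(z, full_matrices=False)
        eig = vt[0]
        mean_profile = z.mean(axis=0)
        if np.dot(eig, mean_profile) < 0:
            eig = -eig
        out[m] = eig
    eg = pd.DataFrame(out, index=expr.columns).T
    eg.index.name = "module"
    return eg


def detect_modules(expr: pd.DataFrame, tom_dissim: np.ndarray, cfg: NetworkConfig) -> ModulePartition:
    """Average-linkage modules on TOM dissimilarity with eigengene merging.

    Initial modules: fixed-height cut at ``cut_height_frac`` of the maximum
    join height, discarding branches smaller than ``min_module_size`` to the
    grey label 0.  Merge step: modules whose eigengene dissimilarity
    (1 - cor) joins below ``merge_cut_height`` are merged; iterated to a
    fixed point.
    """
    n = tom_dissim.shape[0]
    if n < cfg.min_module_size:
        return ModulePartition(np.zeros(n, dtype=int), list(expr.index),
                               pd.DataFrame(columns=expr.columns), np.empty((0, 4)))
    condensed = squareform(np.clip(tom_dissim, 0, None), checks=False)
    z = average(condensed)
    # Adaptive initial cut: the single fixed height can leave two tight
    # modules fused just below the noise-attachment joins, so scan a small
    # grid of heights and keep the highest cut that resolves the most
    # valid-size branches.
    max_h = z[:, 2].max()
    best_raw, best_n = None, -1
    for frac in np.arange(cfg.cut_height_frac, 0.89, -0.01):
        raw = fcluster(z, t=frac * max_h, criterion="distance")
        n_valid = int(np.sum(np.bincount(raw)[1:] >= cfg.min_module_size))
        if n_valid > best_n:
            best_raw, best_n = raw, n_valid
    raw = best_raw
    labels = np.zeros(n, dtype=int)
    next_id = 1
    for m in np.unique(raw):
        idx = raw == m
        if idx.sum() >= cfg.min_module_size:
            labels[idx] = next_id
            next_id += 1
    # iterative eigengene merging
    while True:
        mods = sorted(set(labels) - {0})
        if len(mods) < 2 or cfg.merge_cut_height <= 0:
            break
        eg = module_eigengene(expr, labels)
        cor = np.corrcoef(eg.to_numpy())
        diss = 1.0 - cor
        zz = average(squareform(np.clip(diss, 0, None), checks=False))
        grouped = fcluster(zz, t=cfg.merge_cut_height, criterion="distance")
        if len(set(grouped)) == len(mods):
            break
        remap = {}
        for gnew in np.unique(grouped):
            members = [mods[i] for i in np.flatnonzero(grouped == gnew)]
            for m in members:
                remap[m] = members[0]
        labels = np.array([remap.get(l, 0) for l in labels])
    # kME pruning: a gene must correlate with its module eigengene
    if cfg.kme_min > 0 and set(labels) - {0}:
        eg = module_eigengene(expr, labels)
        x = expr.to_numpy(dtype=float)
        for m in sorted(set(labels) - {0}):
            idx = np.flatnonzero(labels == m)
            e = eg.loc[m].to_numpy()
            ec = e - e.mean()
            en = np.linalg.norm(ec)
            for i in idx:
                g = x[i] - x[i].mean()
                gn = np.linalg.norm(g)
                kme = float(g @ ec / (gn * en)) if gn > 0 and en > 0 else 0.0
                if abs(kme) < cfg.kme_min:
                    labels[i] = 0
            if (labels == m).sum() < cfg.min_module_size:
                labels[labels == m] = 0
    # relabel contiguously by decreasing size
    mods = sorted(set(labels) - {0}, key=lambda m: (-(labels == m).sum(), m))
    remap = {m: i + 1 for i, m in enumerate(mods)}
    labels = np.array([remap.get(l, 0) for l in labels])
    eg = module_eigengene(expr, labels) if set(labels) - {0} else pd.DataFrame(columns=expr.columns)
    return ModulePartition(labels, list(expr.index), eg, z)


def module_trait_correlation(
    eigengenes: pd.DataFrame, traits: pd.DataFrame, alpha: float = 0.05
) -> pd.DataFrame:
    """Spearman rho and asymptotic p per (module, trait); stars per convention."""
    rows = []
    for m in eigengenes.index:
        for t in traits.columns:
            rho, p = spearman(eigengenes.loc[m].to_numpy(), traits[t].to_numpy())
            stars = ""
            if np.isfinite(p):
                if p < 0.001:
                    stars = "**"
                elif p < alpha:
                    stars = "*"
            rows.append({"module": m, "trait": t, "rho": rho, "p": p,
                         "significant": bool(np.isfinite(p) and p < alpha), "stars": stars})
    return pd.DataFrame(rows)
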