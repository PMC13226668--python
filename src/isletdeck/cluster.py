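"""Normalization, feature selection, embedding, covariate-aligned graph
clustering, marker-based annotation, and one-vs-rest marker tests.

The stack mirrors the droplet-atlas standard: library-size log-normalization
(scale factor 10,000), top-2000 highly variable genes by trend-standardized
variance, PCA on centered/scaled features, iterative centroid-offset
covariate alignment in PC space, a shared-nearest-neighbor (Jaccard) graph
over the 20 nearest neighbors pruned at 1/15, and modularity community
detection at a given resolution.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import igraph as ig
import leidenalg
import numpy as np
import pandas as pd
import scipy.sparse as sp
import statsmodels.api as sm
from scipy.stats import chi2
from sklearn.neighbors import NearestNeighbors

from ._stats import bh_fdr
from .io_cohort import CountsMatrix, FloatMatrix

HORMONE_GENES = ("INS", "GCG", "SST", "PPY", "GHRL")

DEFAULT_MARKER_PANEL = {
    "beta": "INS",
    "alpha": "GCG",
    "delta": "SST",
    "gamma": "PPY",
    "epsilon": "GHRL",
    "ductal": "KRT19",
    "acinar": "REG1B",
    "stellate": "COL1A1",
    "quiescent_stellate": "FABP4",
    "endothelial": "PLVAP",
    "schwann": "NGFR",
    "immune": "C1QC",
    "mast": "TPSB2",
    "proliferating": "TOP2A",
}


@dataclass
class NormalizedMatrix:
    """log1p of per-cell scaled counts (genes x cells, sparse)."""

    values: sp.csr_matrix
    gene_ids: list[str]
    barcode_ids: list[str]
    scale_factor: float = 10_000.0


def lognormalize(m: CountsMatrix | FloatMatrix, scale_factor: float = 10_000.0) -> NormalizedMatrix:
    """x_gc = ln(1 + scale_factor * n_gc / N_c); zero-total cells map to zeros."""
    csc = sp.csc_matrix(m.values, dtype=float)
    totals = np.asarray(csc.sum(axis=0)).ravel()
    inv = np.where(totals > 0, 1.0 / np.maximum(totals, 1e-300), 0.0)
    scaled = csc @ sp.diags(inv * scale_factor)
    scaled.data = np.log1p(scaled.data)
    return NormalizedMatrix(scaled.tocsr(), list(m.gene_ids), list(m.barcode_ids), scale_factor)


def select_hvg(nm: NormalizedMatrix, n: int = 2000, n_bins: int = 20) -> list[str]:
    """Top-n genes by trend-standardized variance.

    Genes are binned by log mean expression; each gene's variance is divided
    by the median variance of its bin (the mean-variance trend), and the
    top-n standardized variances win.  Ties break by gene id.
    """
    g = len(nm.gene_ids)
    if n > g:
        raise ValueError(f"requested {n} HVGs from {g} genes")
    x = nm.values
    mean = np.asarray(x.mean(axis=1)).ravel()
    sq = np.asarray(x.multiply(x).mean(axis=1)).ravel()
    var = np.maximum(sq - mean**2, 0.0)
    std_var = np.zeros(g)
    expressed = mean > 0
    logm = np.log1p(mean[expressed])
    if expressed.sum():
        bins = np.quantile(logm, np.linspace(0, 1, min(n_bins, max(expressed.sum(), 2)) + 1))
        which = np.clip(np.searchsorted(bins, logm, side="right") - 1, 0, len(bins) - 2)
        trend = np.ones_like(logm)
        for b in np.unique(which):
            med = np.median(var[expressed][which == b])
            trend[which == b] = med if med > 0 else 1.0
        std_var[expressed] = var[expressed] / trend
    order = sorted(range(g), key=lambda i: (-std_var[i], nm.gene_ids[i]))
    return [nm.gene_ids[i] for i in order[:n]]


@dataclass
class Embedding:
    coords: np.ndarray  # cells x PCs
    explained_variance_ratio: np.ndarray
    hvg: list[str]
    barcode_ids: list[str]


def embed_pca(nm: NormalizedMatrix, hvg: Sequence[str], n_pcs: int = 100) -> Embedding:
    """Centered, unit-scaled PCA on the HVG submatrix.

    Sign convention: the largest-magnitude gene loading of each PC is made
    positive, so embeddings are reproducible across runs.
    """
    idx = [nm.gene_ids.index(g) for g in hvg]
    x = np.asarray(nm.values[idx, :].todense()).T  # cells x genes
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    xs = (x - mu) / sd
    n_pcs = min(n_pcs, min(xs.shape))
    u, s, vt = np.linalg.svd(xs, full_matrices=False)
    u, s, vt = u[:, :n_pcs], s[:n_pcs], vt[:n_pcs]
    # orient: largest-|loading| positive per PC
    for k in range(n_pcs):
        j = np.argmax(np.abs(vt[k]))
        if vt[k, j] < 0:
            vt[k] *= -1
            u[:, k] *= -1
    coords = u * s
    total_var = (xs**2).sum()
    evr = (s**2) / total_var if total_var > 0 else np.zeros(n_pcs)
    return Embedding(coords, evr, list(hvg), list(nm.barcode_ids))


def covariate_align(
    e: Embedding,
    covariates: pd.DataFrame,
    n_iter: int = 10,
    n_clusters: int = 30,
    tol: float = 1e-4,
    min_level_cells: int = 5,
    seed: int = 0,
) -> Embedding:
    """Iterative soft-kmeans centroid-offset alignment over categorical covariates.

    At each iteration cells are softly assigned to ``n_clusters`` centroids;
    responsibilities are reweighted toward covariate balance within each
    cluster (clusters that capture a single batch would otherwise see no
    within-cluster offset); then, for every (cluster, covariate level), the
    responsibility-weighted offset between the level centroid and the cluster
    centroid is subtracted from cells of that level.  Balanced covariates
    imply near-zero correction.
    """
    x = e.coords.copy()
    n, d = x.shape
    rng = np.random.default_rng(seed)
    k = min(n_clusters, max(2, n // 10))
    centroids = x[rng.choice(n, size=k, replace=False)]
    cov = covariates.copy()
    for col in cov.columns:
        vc = cov[col].value_counts()
        rare = vc[vc < min_level_cells].index
        if len(rare):
            cov[col] = cov[col].where(~cov[col].isin(rare), "other")
    sigma = np.median(np.var(x, axis=0)) * d + 1e-12
    for _ in range(n_iter):
        d2 = ((x[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
        logits = -d2 / sigma
        logits -= logits.max(axis=1, keepdims=True)
        r = np.exp(logits)
        r /= r.sum(axis=1, keepdims=True)
        # diversity reweighting: inflate responsibilities of under-represented
        # covariate levels within each cluster so batch-pure clusters still
        # expose a within-cluster offset
        for col in cov.columns:
            cluster_mass = r.sum(axis=0)
            for level in cov[col].unique():
                mask = (cov[col] == level).to_numpy()
                observed = r[mask].sum(axis=0)
                expected = cluster_mass * mask.mean()
                w = (expected + 1.0) / (observed + 1.0)
                r[mask] *= w
        r /= r.sum(axis=1, keepdims=True)
        centroids = (r.T @ x) / np.maximum(r.sum(axis=0)[:, None], 1e-12)
        correction = np.zeros_like(x)
        for col in cov.columns:
            for level in cov[col].unique():
                mask = (cov[col] == level).to_numpy()
                if mask.sum() == 0:
                    continue
                w_level = r[mask]
                denom = np.maximum(w_level.sum(axis=0)[:, None], 1e-12)
                level_centroid = (w_level.T @ x[mask]) / denom
                offset = level_centroid - centroids  # k x d
                correction[mask] += w_level @ offset
        x = x - correction
        if np.linalg.norm(correction) < tol:
            break
    return Embedding(x, e.explained_variance_ratio, e.hvg, e.barcode_ids)


@dataclass
class Clustering:
    labels: np.ndarray  # contiguous ints from 0, ordered by decreasing size
    resolution: float
    k_neighbors: int
    seed: int
    modularity: float


def snn_cluster(
    e: Embedding,
    k: int = 20,
    resolution: float = 1.0,
    prune: float = 1.0 / 15.0,
    seed: int = 0,
) -> Clustering:
    """SNN (Jaccard) graph over k nearest neighbors + modularity communities."""
    n = e.coords.shape[0]
    if k >= n:
        raise ValueError("k must be smaller than the number of cells")
    nn = NearestNeighbors(n_neighbors=k).fit(e.coords)
    _, idx = nn.kneighbors(e.coords)  # includes self
    rows = np.repeat(np.arange(n), k)
    a = sp.csr_matrix((np.ones(n * k), (rows, idx.ravel())), shape=(n, n))
    inter = (a @ a.T).tocoo()
    jac = inter.data / (2 * k - inter.data)
    keep = (jac >= prune) & (inter.row != inter.col)
    g = ig.Graph(
        n=n,
        edges=list(zip(inter.row[keep].tolist(), inter.col[keep].tolist())),
        edge_attrs={"weight": jac[keep].tolist()},
    ).simplify(combine_edges="max")
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        weights="weight",
        resolution_parameter=resolution,
        seed=seed,
        n_iterations=2,
    )
    labels = np.asarray(part.membership)
    # relabel by decreasing cluster size (stable)
    sizes = pd.Series(labels).value_counts()
    remap = {old: new for new, old in enumerate(sizes.index)}
    labels = np.array([remap[l] for l in labels])
    return Clustering(labels, resolution, k, seed, float(part.quality()))


def annotate_clusters(
    c: Clustering,
    nm: NormalizedMatrix,
    panel: dict[str, str] | None = None,
    z_min: float = 1.0,
) -> pd.DataFrame:
    """Assign each cluster the type of its max-z marker; flag multi-hormone clusters.

    Marker z-scores are computed across clusters on cluster-mean normalized
    expression.  Clusters with >= 2 hormone markers above ``z_min`` are
    flagged as doublet-suspect ("multi_hormone").
    """
    panel = panel if panel is not None else DEFAULT_MARKER_PANEL
    if not panel:
        raise ValueError("marker panel is empty")
    present = {t: g for t, g in panel.items() if g in nm.gene_ids}
    missing = sorted(set(panel.values()) - {g for g in present.values()})
    if not present:
        raise ValueError("no panel markers present in the gene universe")
    genes = list(present.values())
    gi = [nm.gene_ids.index(g) for g in genes]
    labels = np.unique(c.labels)
    means = np.zeros((len(labels), len(genes)))
    dense = np.asarray(nm.values[gi, :].todense())
    for li, l in enumerate(labels):
        means[li] = dense[:, c.labels == l].mean(axis=1)
    mu = means.mean(axis=0)
    sd = means.std(axis=0)
    sd[sd == 0] = 1.0
    z = (means - mu) / sd
    types = list(present)
    hormones = [i for i, g in enumerate(genes) if g in HORMONE_GENES]
    rows = []
    for li, l in enumerate(labels):
        best = int(np.argmax(z[li]))
        assigned = types[best] if z[li, best] > z_min else "unassigned"
        n_h = int((z[li, hormones] > z_min).sum()) if hormones else 0
        rows.append(
            {"cluster": int(l), "cell_type": assigned, "best_marker": genes[best],
             "best_z": float(z[li, best]), "multi_hormone": n_h >= 2,
             "missing_markers": ",".join(missing)}
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# one-vs-rest marker tests


def _lrt_logistic(y: np.ndarray, x_full: np.ndarray, x_null: np.ndarray) -> tuple[float, bool]:
    """1-df LRT p for the last column of x_full; returns (p, ridge_flag)."""
    flagged = False

    def fit_llf(x):
        nonlocal flagged
        model = sm.Logit(y, x)
        try:
            with np.errstate(all="ignore"):
                res = model.fit(disp=0, maxiter=100)
            if not res.mle_retvals.get("converged", True) or np.abs(res.params).max() > 25:
                raise ValueError("separation")
            return res.llf
        except Exception:
            flagged = True
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = model.fit_regularized(alpha=1e-3, L1_wt=0.0, disp=0, maxiter=200)
            return model.loglike(np.asarray(res.params))

    llf_full = fit_llf(x_full)
    llf_null = fit_llf(x_null)
    stat = max(2 * (llf_full - llf_null), 0.0)
    return float(chi2.sf(stat, 1)), flagged


def _nb_alpha_pearson(y: np.ndarray, x: np.ndarray, offset: np.ndarray) -> float:
    """Crude per-gene NB dispersion from Poisson-fit Pearson residuals."""
    try:
        res = sm.GLM(y, x, family=sm.families.Poisson(), offset=offset).fit()
        mu = res.fittedvalues
        df = max(len(y) - x.shape[1], 1)
        excess = ((y - mu) ** 2 - mu) / np.maximum(mu**2, 1e-8)
        return float(np.clip(excess.sum() / df, 1e-6, 10.0))
    except Exception:
        return 0.1


def _lrt_negbinom(
    y: np.ndarray, x_full: np.ndarray, x_null: np.ndarray, offset: np.ndarray
) -> tuple[float, bool]:
    alpha = _nb_alpha_pearson(y, x_null, offset)
    fam = sm.families.NegativeBinomial(alpha=alpha)
    try:
        with np.errstate(all="ignore"):
            llf_full = sm.GLM(y, x_full, family=fam, offset=offset).fit().llf
            llf_null = sm.GLM(y, x_null, family=fam, offset=offset).fit().llf
        stat = max(2 * (llf_full - llf_null), 0.0)
        return float(chi2.sf(stat, 1)), False
    except Exception:
        return 1.0, True


def marker_de(
    nm: NormalizedMatrix,
    labels: np.ndarray,
    target: int,
    covariates: Optional[pd.DataFrame] = None,
    family: str = "logistic",
    counts: Optional[CountsMatrix] = None,
    genes: Optional[Sequence[str]] = None,
    lfc_min: float = 0.25,
    fdr_max: float = 0.01,
    min_cells: int = 10,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """One-vs-rest marker test for one cluster.

    logistic: per gene, LRT of cluster membership regressed on covariates
    plus the gene's normalized expression vs covariates alone.
    negbinom: per gene, NB regression of raw counts on membership +
    covariates with a log-total offset, LRT on membership.
    log2FC uses mean expm1 normalized expression with a pseudocount.
    """
    y = (labels == target).astype(float)
    if y.sum() < min_cells:
        raise ValueError(f"target cluster has fewer than {min_cells} cells")
    n = len(y)
    if covariates is not None and len(covariates):
        design = pd.get_dummies(covariates, drop_first=True).astype(float).to_numpy()
    else:
        design = np.empty((n, 0))
    x_base = np.column_stack([np.ones(n), design])
    gene_list = list(genes) if genes is not None else list(nm.gene_ids)
    gi = [nm.gene_ids.index(g) for g in gene_list]
    norm_dense = np.asarray(nm.values[gi, :].todense())
    expm1 = np.expm1(norm_dense)
    in_mask = y.astype(bool)
    mean_in = expm1[:, in_mask].mean(axis=1)
    mean_out = expm1[:, ~in_mask].mean(axis=1)
    log2fc = np.log2((mean_in + pseudocount) / (mean_out + pseudocount))

    if family == "negbinom":
        if counts is None:
            raise ValueError("negbinom family requires raw counts")
        raw = np.asarray(counts.values[[counts.gene_ids.index(g) for g in gene_list], :].todense())
        offset = np.log(np.maximum(raw.sum(axis=0), 1.0))
        x_full = np.column_stack([x_base, y])

    rows = []
    for i, g in enumerate(gene_list):
        if family == "logistic":
            expr = norm_dense[i]
            if expr.std() == 0:
                p, flag = 1.0, False
            else:
                x_full_g = np.column_stack([x_base, expr])
                p, flag = _lrt_logistic(y, x_full_g, x_base)
        elif family == "negbinom":
            p, flag = _lrt_negbinom(raw[i], x_full, x_base, offset)
        else:
            raise ValueError(f"unknown family {family!r}")
        rows.append({"gene": g, "log2fc": float(log2fc[i]), "p": p, "ridge_fallback": flag})
    out = pd.DataFrame(rows)
    out["fdr"] = bh_fdr(out["p"].to_numpy())
    out["significant"] = (out["log2fc"] >= lfc_min) & (out["fdr"] <= fdr_max)
    return out
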