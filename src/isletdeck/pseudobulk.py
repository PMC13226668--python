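"""Pseudobulk aggregation and negative-binomial GLM differential expression.

Single-cell counts are summed per (donor, cell type) so donors — not cells —
are the replication unit.  Per gene, a NB log-linear model with a log
library-size offset is fitted on state plus chemistry, sex, ancestry, scaled
age, and scaled BMI; the per-gene dispersion MLE is shrunk toward the
common (all-gene) dispersion, and contrasts are tested by likelihood-ratio
tests with Benjamini-Hochberg FDR within contrast.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import gammaln
from scipy.stats import chi2

from ._stats import bh_fdr
from .io_cohort import CountsMatrix

DEFAULT_COVARIATES = ("chemistry", "sex", "ancestry", "age_scaled", "bmi_scaled")


@dataclass
class PseudobulkMatrix:
    counts: pd.DataFrame  # genes x samples, integer
    design: pd.DataFrame  # per-sample covariates, index = sample ids
    cells_per_sample: pd.Series


def aggregate_pseudobulk(
    cells: pd.DataFrame,
    matrices: dict[str, CountsMatrix],
    donors: pd.DataFrame,
    min_cells: int = 10,
) -> PseudobulkMatrix:
    """Sum kept single-cell counts per (donor, cell type) sample.

    Samples with fewer than ``min_cells`` contributing cells are dropped.
    Age and BMI are standardized over the retained samples (mean 0, sd 1).
    The integer identity pseudobulk == column sum of its cells is exact.
    """
    keep = cells[(~cells["filtered"]) & cells["donor_id"].notna() & cells["cell_type"].notna()]
    donor_info = donors.set_index("donor_id")
    missing = set(keep["donor_id"]) - set(donor_info.index)
    if missing:
        raise KeyError(f"missing covariates for donor(s): {sorted(missing)}")
    gene_ids = matrices[next(iter(matrices))].gene_ids
    cols: dict[str, np.ndarray] = {}
    n_cells: dict[str, int] = {}
    meta: dict[str, dict] = {}
    for (donor, ctype), grp in keep.groupby(["donor_id", "cell_type"], observed=True):
        if len(grp) < min_cells:
            continue
        acc = np.zeros(len(gene_ids), dtype=np.int64)
        for lib, sub in grp.groupby("library_id"):
            m = matrices[lib]
            pos = {b: i for i, b in enumerate(m.barcode_ids)}
            idx = [pos[b] for b in sub["barcode_id"]]
            acc += np.asarray(m.values[:, idx].sum(axis=1)).ravel().astype(np.int64)
        sid = f"{donor}|{ctype}"
        cols[sid] = acc
        n_cells[sid] = len(grp)
        d = donor_info.loc[donor]
        meta[sid] = {
            "donor_id": donor, "cell_type": ctype, "state": d["state"],
            "chemistry": d["chemistry"], "sex": d["sex"], "ancestry": d["ancestry"],
            "age": float(d["age"]), "bmi": float(d["bmi"]),
        }
    if not cols:
        raise ValueError("no pseudobulk samples survive the min_cells filter")
    counts = pd.DataFrame(cols, index=gene_ids)
    design = pd.DataFrame(meta).T
    for col in ("age", "bmi"):
        v = design[col].astype(float)
        sd = v.std(ddof=0)
        design[f"{col}_scaled"] = (v - v.mean()) / (sd if sd > 0 else 1.0)
    return PseudobulkMatrix(counts, design, pd.Series(n_cells))


def cpm_log(counts: pd.DataFrame, prior: float = 0.5) -> pd.DataFrame:
    """log2 CPM with a prior count: log2((n + prior) / (N + 2*prior) * 1e6)."""
    totals = counts.sum(axis=0).astype(float)
    if (totals <= 0).any():
        raise ValueError("zero column total in pseudobulk counts")
    return np.log2((counts + prior).div(totals + 2 * prior, axis=1) * 1e6)


# ---------------------------------------------------------------------------
# NB GLM machinery


def _nb_loglik(y: np.ndarray, mu: np.ndarray, alpha: float) -> float:
    """Negative binomial log-likelihood with dispersion alpha (var = mu + alpha mu^2)."""
    r = 1.0 / alpha
    mu = np.maximum(mu, 1e-10)
    return float(
        np.sum(
            gammaln(y + r) - gammaln(r) - gammaln(y + 1)
            + r * np.log(r / (r + mu)) + y * np.log(mu / (r + mu))
        )
    )


def _irls_nb(
    y: np.ndarray, x: np.ndarray, offset: np.ndarray, alpha: float,
    tol: float = 1e-8, max_iter: int = 50,
) -> tuple[np.ndarray, np.ndarray]:
    """IRLS for a NB log-linear model with offset; returns (beta, mu)."""
    n, p = x.shape
    beta = np.zeros(p)
    beta[0] = np.log(np.maximum(y.mean(), 0.1)) - offset.mean() if p else 0.0
    eta = x @ beta + offset
    mu = np.exp(np.clip(eta, -30, 30))
    for _ in range(max_iter):
        w = mu / (1.0 + alpha * mu)
        z = (eta - offset) + (y - mu) / np.maximum(mu, 1e-10)
        xtw = x.T * w
        try:
            beta_new = np.linalg.solve(xtw @ x + 1e-10 * np.eye(p), xtw @ z)
        except np.linalg.LinAlgError:
            beta_new = np.linalg.lstsq(xtw @ x, xtw @ z, rcond=None)[0]
        step = beta_new - beta
        beta = beta_new
        eta = np.clip(x @ beta + offset, -30, 30)
        mu = np.exp(eta)
        if np.max(np.abs(step)) < tol:
            break
    return beta, mu


def _dispersion_mle(
    y: np.ndarray, x: np.ndarray, offset: np.ndarray,
    log_alpha_bounds: tuple[float, float] = (-8.0, 3.0),
) -> float:
    """Per-gene dispersion MLE by profile likelihood over log(alpha)."""

    def neg_ll(log_alpha: float) -> float:
        alpha = float(np.exp(log_alpha))
        _, mu = _irls_nb(y, x, offset, alpha)
        return -_nb_loglik(y, mu, alpha)

    res = minimize_scalar(neg_ll, bounds=log_alpha_bounds, method="bounded",
                          options={"xatol": 5e-2})
    return float(np.exp(res.x))


def _design_matrix(
    design: pd.DataFrame, factor: str, covariates: Sequence[str], merge: Optional[tuple] = None
) -> tuple[np.ndarray, list[str], list[str]]:
    """Intercept + factor dummies (optionally merging two levels) + covariates."""
    df = design.copy()
    if merge is not None:
        a, b = merge
        df[factor] = df[factor].replace({b: a})
    parts = [pd.Series(1.0, index=df.index, name="intercept")]
    levels = sorted(df[factor].astype(str).unique())
    for lv in levels[1:]:
        parts.append((df[factor].astype(str) == lv).astype(float).rename(f"{factor}[{lv}]"))
    for cov in covariates:
        if cov not in df.columns:
            continue
        col = df[cov]
        if col.dtype == object or str(col.dtype) == "category":
            for lv in sorted(col.astype(str).unique())[1:]:
                parts.append((col.astype(str) == lv).astype(float).rename(f"{cov}[{lv}]"))
        else:
            parts.append(col.astype(float).rename(cov))
    xdf = pd.concat(parts, axis=1)
    x = xdf.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        # identify aliased columns greedily
        keep, aliased = [], []
        for j in range(x.shape[1]):
            trial = x[:, keep + [j]]
            if np.linalg.matrix_rank(trial) > len(keep):
                keep.append(j)
            else:
                aliased.append(xdf.columns[j])
        raise ValueError(f"rank-deficient design; aliased columns: {aliased}")
    return x, list(xdf.columns), levels


@dataclass
class NBGLMFit:
    counts: pd.DataFrame
    design: pd.DataFrame
    factor: str
    covariates: tuple[str, ...]
    offsets: np.ndarray
    alphas: pd.Series  # shrunk per-gene dispersion
    common_alpha: float
    x_full: np.ndarray
    columns: list[str]
    levels: list[str]
    betas: pd.DataFrame  # per-gene coefficients of the full model


def fit_nb_glm(
    pb_counts: pd.DataFrame,
    design: pd.DataFrame,
    factor: str = "state",
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    prior_df: float = 10.0,
    lib_sizes: Optional[pd.Series] = None,
) -> NBGLMFit:
    """Fit per-gene NB GLMs with dispersion shrinkage.

    The per-gene dispersion MLE is averaged (on the log scale) into a common
    dispersion; each gene's working dispersion is the weighted combination
    with weight prior_df / (prior_df + residual_df) on the common value.
    ``lib_sizes`` supplies per-sample library sizes for the offset when the
    count frame is a gene subset of a larger matrix; defaults to the frame's
    own column sums.
    """
    counts = pb_counts.loc[:, design.index]
    y_all = counts.to_numpy(dtype=float)
    if lib_sizes is not None:
        offsets = np.log(np.maximum(lib_sizes.loc[design.index].to_numpy(dtype=float), 1.0))
    else:
        offsets = np.log(np.maximum(y_all.sum(axis=0), 1.0))
    x, columns, levels = _design_matrix(design, factor, covariates)
    n, p = x.shape
    for lv in levels:
        if (design[factor].astype(str) == lv).sum() < 2:
            raise ValueError(f"factor level {lv!r} has fewer than 2 samples")
    raw_alphas = np.array([
        _dispersion_mle(y_all[i], x, offsets) for i in range(y_all.shape[0])
    ])
    common = float(np.exp(np.mean(np.log(raw_alphas))))
    resid_df = max(n - p, 1)
    w = prior_df / (prior_df + resid_df)
    shrunk = np.exp(w * np.log(common) + (1 - w) * np.log(raw_alphas))
    betas = np.zeros((y_all.shape[0], p))
    for i in range(y_all.shape[0]):
        betas[i], _ = _irls_nb(y_all[i], x, offsets, shrunk[i])
    return NBGLMFit(
        counts=counts, design=design, factor=factor, covariates=tuple(covariates),
        offsets=offsets, alphas=pd.Series(shrunk, index=counts.index),
        common_alpha=common, x_full=x, columns=columns, levels=levels,
        betas=pd.DataFrame(betas, index=counts.index, columns=columns),
    )


def test_contrast(fit: NBGLMFit, level_a: str, level_b: str) -> pd.DataFrame:
    """LRT of level_a vs level_b on the factor coefficient; log2FC = (a-b)/ln2.

    The reduced model merges the two contrasted levels; covariates and any
    third factor level stay in both models, so the test has one degree of
    freedom per gene.
    """
    for lv in (level_a, level_b):
        if lv not in fit.levels:
            raise ValueError(f"level {lv!r} not in factor levels {fit.levels}")
    merge = (min(level_a, level_b), max(level_a, level_b))
    x_red, _, _ = _design_matrix(fit.design, fit.factor, fit.covariates, merge=merge)
    y_all = fit.counts.to_numpy(dtype=float)

    def coef(level: str, i: int) -> float:
        name = f"{fit.factor}[{level}]"
        return float(fit.betas.iloc[i][name]) if name in fit.columns else 0.0

    rows = []
    for i, g in enumerate(fit.counts.index):
        alpha = float(fit.alphas.iloc[i])
        _, mu_full = _irls_nb(y_all[i], fit.x_full, fit.offsets, alpha)
        _, mu_red = _irls_nb(y_all[i], x_red, fit.offsets, alpha)
        ll_full = _nb_loglik(y_all[i], mu_full, alpha)
        ll_red = _nb_loglik(y_all[i], mu_red, alpha)
        stat = max(2.0 * (ll_full - ll_red), 0.0)
        p = float(chi2.sf(stat, 1))
        lfc = (coef(level_a, i) - coef(level_b, i)) / np.log(2.0)
        rows.append({"gene": g, "log2fc": lfc, "stat": stat, "p": p})
    out = pd.DataFrame(rows)
    out["fdr"] = bh_fdr(out["p"].to_numpy())
    out.attrs["contrast"] = f"{level_a}_vs_{level_b}"
    return out


def call_degs(res: pd.DataFrame, lfc_min: float = 0.585, fdr_max: float = 0.05) -> dict:
    """Split a DE result into up/down gene sets at the stated thresholds."""
    sig = res[(res["log2fc"].abs() >= lfc_min) & (res["fdr"] <= fdr_max)]
    return {
        "up": list(sig.loc[sig["log2fc"] > 0, "gene"]),
        "down": list(sig.loc[sig["log2fc"] < 0, "gene"]),
    }


def signature_genes(
    one_vs_rest: dict[str, pd.DataFrame],
    pairwise: dict[tuple[str, str], pd.DataFrame],
    preset: str = "methods",
) -> dict[str, list[str]]:
    """Per-cell-type signature sets.

    methods preset: up in one-vs-rest at (log2FC >= 0.585, FDR <= 5 %) AND up
    vs every other type at |log2FC| >= 1 (uniqueness rule).
    results8fold preset: one-vs-rest log2FC >= 3 at FDR < 5 %.
    """
    out: dict[str, list[str]] = {}
    types = list(one_vs_rest)
    for t in types:
        ovr = one_vs_rest[t]
        if preset == "results8fold":
            sel = ovr[(ovr["log2fc"] >= 3.0) & (ovr["fdr"] < 0.05)]
            out[t] = sorted(sel["gene"])
            continue
        if preset != "methods":
            raise ValueError(f"unknown preset {preset!r}")
        base = set(ovr.loc[(ovr["log2fc"] >= 0.585) & (ovr["fdr"] <= 0.05), "gene"])
        for other in types:
            if other == t or not base:
                continue
            key = (t, other) if (t, other) in pairwise else (other, t)
            pw = pairwise[key]
            sign = 1.0 if key == (t, other) else -1.0
            ok = set(pw.loc[(sign * pw["log2fc"] >= 1.0) & (pw["fdr"] <= 0.05), "gene"])
            base &= ok
        out[t] = sorted(base)
    return out
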