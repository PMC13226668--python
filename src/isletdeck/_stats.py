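"""Shared statistical primitives: BH-FDR, Tukey HSD, Games-Howell, one-way ANOVA.

Tukey and Games-Howell p-values come from the studentized-range distribution
(scipy.stats.studentized_range); the surrounding bookkeeping (pairing,
Welch-Satterthwaite df, Bonferroni) is done here so every module shares one
implementation.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats


def bh_fdr(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    n = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / (np.arange(n) + 1)
    # enforce monotonicity from the largest p downwards
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out


def one_way_anova(groups: Sequence[np.ndarray]) -> tuple[float, float]:
    """One-way fixed-effects ANOVA; returns (F, p).

    Degenerate all-equal input (0/0 F ratio) is reported as no evidence
    against the null: F = 0, p = 1.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:
        return 0.0, 1.0
    with np.errstate(invalid="ignore"):
        f, p = stats.f_oneway(*arrays)
    if not np.isfinite(f):
        return 0.0, 1.0
    return float(f), float(p)


@dataclass
class PairwiseResult:
    group_a: str
    group_b: str
    diff: float
    p: float


def tukey_hsd(groups: Mapping[str, np.ndarray]) -> list[PairwiseResult]:
    """Tukey HSD pairwise comparisons via the studentized-range distribution.

    Uses the pooled within-group variance (equal-variance assumption) and
    supports unbalanced designs through the Tukey-Kramer standard error.
    """
    names = list(groups)
    data = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    k = len(names)
    if k < 2:
        raise ValueError("need at least two groups")
    ns = {g: len(data[g]) for g in names}
    means = {g: float(np.mean(data[g])) for g in names}
    df_w = sum(ns.values()) - k
    if df_w <= 0:
        raise ValueError("no residual degrees of freedom")
    ss_w = sum(float(np.sum((data[g] - means[g]) ** 2)) for g in names)
    ms_w = ss_w / df_w
    out = []
    for a, b in combinations(names, 2):
        diff = means[a] - means[b]
        se = np.sqrt(ms_w / 2.0 * (1.0 / ns[a] + 1.0 / ns[b]))
        if se == 0:
            p = 1.0 if diff == 0 else 0.0
        else:
            q = abs(diff) / se
            p = float(stats.studentized_range.sf(q, k, df_w))
        out.append(PairwiseResult(a, b, diff, min(max(p, 0.0), 1.0)))
    return out


def games_howell(groups: Mapping[str, np.ndarray]) -> list[PairwiseResult]:
    """Games-Howell pairwise comparisons (Welch variances, studentized range).

    Each pair uses its own Welch-Satterthwaite degrees of freedom, so the
    procedure stays calibrated under heteroscedasticity.
    """
    names = list(groups)
    data = {g: np.asarray(v, dtype=float) for g, v in groups.items()}
    k = len(names)
    if k < 2:
        raise ValueError("need at least two groups")
    for g in names:
        if len(data[g]) < 3:
            raise ValueError(f"group {g}: needs >= 3 values")
    out = []
    for a, b in combinations(names, 2):
        xa, xb = data[a], data[b]
        na, nb = len(xa), len(xb)
        va, vb = np.var(xa, ddof=1), np.var(xb, ddof=1)
        diff = float(np.mean(xa) - np.mean(xb))
        se2 = va / na + vb / nb
        if se2 == 0:
            p = 1.0 if diff == 0 else 0.0
        else:
            df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
            q = abs(diff) / np.sqrt(se2 / 2.0)
            p = float(stats.studentized_range.sf(q, k, df))
        out.append(PairwiseResult(a, b, diff, min(max(p, 0.0), 1.0)))
    return out


def spearman(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Spearman rho with asymptotic p; (nan, nan) for constant input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.all(x == x[0]) or np.all(y == y[0]):
        return float("nan"), float("nan")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def anova_tukey_table(
    values: pd.Series, labels: pd.Series, bonferroni_m: int = 1
) -> tuple[float, float, pd.DataFrame]:
    """One-way ANOVA plus Tukey HSD on a labelled series.

    Returns (F, p_anova, pairwise frame with Bonferroni-adjusted p).
    """
    groups = {str(g): values[labels == g].to_numpy() for g in pd.unique(labels)}
    groups = {g: v for g, v in groups.items() if len(v) >= 2}
    if len(groups) < 2:
        raise ValueError("need >= 2 groups with >= 2 observations")
    f, p = one_way_anova(list(groups.values()))
    rows = [
        {
            "group_a": r.group_a,
            "group_b": r.group_b,
            "diff": r.diff,
            "p": r.p,
            "p_adj": min(r.p * bonferroni_m, 1.0),
        }
        for r in tukey_hsd(groups)
    ]
    return f, p, pd.DataFrame(rows)
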