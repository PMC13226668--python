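"""Genotype-likelihood demultiplexing of pooled droplets.

Each droplet's variant-overlapping base calls are scored against every
candidate donor (singlet) and unordered donor pair (doublet, mixing
proportion alpha) using genotype posteriors:

    log L(m1, m2, a) = sum_v log sum_{g1,g2} [ prod_i ((1-a) P(b_i|g1) + a P(b_i|g2)) ]
                                     P_{m1,v}(g1) P_{m2,v}(g2)

with the per-call error model P(A|g) = (g/2)(1-eps) + (1-g/2) eps.  A droplet
is called a doublet only when the best doublet log-likelihood beats the best
singlet by a configurable margin (nats).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd

from .io_cohort import flag_cells

GENOTYPE_CERTAINTY = 1.0 - 1e-6


def read_call_likelihood(call: str, g: int, eps: float) -> float:
    """P(base call | alt dosage g, error rate eps); calls are R, A, or O."""
    if g not in (0, 1, 2):
        raise ValueError("dosage must be 0, 1, or 2")
    if call == "A":
        return (g / 2.0) * (1 - eps) + (1 - g / 2.0) * eps
    if call == "R":
        return (1 - g / 2.0) * (1 - eps) + (g / 2.0) * eps
    if call == "O":
        return eps
    raise ValueError(f"unknown base call {call!r}")


def genotype_posteriors(dosages: pd.DataFrame, certainty: float = GENOTYPE_CERTAINTY) -> dict:
    """Hard dosages -> per-(donor, variant) posterior triples.

    The residual 1-certainty mass is split over the other two genotypes so a
    single miscalled read cannot drive a donor's likelihood to -inf.
    """
    post = {}
    resid = (1.0 - certainty) / 2.0
    for donor in dosages.columns:
        arr = np.full((len(dosages), 3), resid)
        g = dosages[donor].to_numpy().astype(int)
        arr[np.arange(len(g)), g] = certainty
        post[donor] = pd.DataFrame(arr, index=dosages.index, columns=[0, 1, 2])
    return post


@dataclass
class DemuxAssignment:
    droplet_id: str
    best_type: str  # singlet | doublet | ambiguous
    best_donors: tuple[str, ...]
    log_likelihoods: dict
    margin: float  # best minus runner-up log-likelihood, >= 0
    n_calls: int = 0


def _call_liks(eps: float) -> tuple[np.ndarray, np.ndarray]:
    """Per-dosage likelihood vectors for ALT and REF calls."""
    pa = np.array([read_call_likelihood("A", g, eps) for g in (0, 1, 2)])
    pr = np.array([read_call_likelihood("R", g, eps) for g in (0, 1, 2)])
    return pa, pr


def assignment_loglik(
    pileup: pd.DataFrame,
    m1: str,
    m2: str,
    alpha: float,
    posteriors: dict,
    eps: float = 0.01,
) -> float:
    """Log-likelihood of a droplet pileup under a (m1, m2, alpha) mixture.

    ``pileup`` rows: variant_id, n_ref, n_alt.  With m1 == m2 (any alpha)
    this collapses to the singlet likelihood.  Variants missing from the
    genotype table are skipped.
    """
    pa, pr = _call_liks(eps)
    p1 = posteriors[m1]
    p2 = posteriors[m2]
    total = 0.0
    for _, row in pileup.iterrows():
        v = row["variant_id"]
        if v not in p1.index:
            continue
        w1 = p1.loc[v].to_numpy()
        w2 = p2.loc[v].to_numpy()
        # per (g1, g2): prod over calls of the mixture probability
        mix_a = (1 - alpha) * pa[:, None] + alpha * pa[None, :]
        mix_r = (1 - alpha) * pr[:, None] + alpha * pr[None, :]
        logmat = row["n_alt"] * np.log(mix_a) + row["n_ref"] * np.log(mix_r)
        m = logmat.max()
        lik = np.exp(logmat - m) * w1[:, None] * w2[None, :]
        total += m + np.log(lik.sum())
    return float(total)


def assign_droplet(
    pileup: pd.DataFrame,
    posteriors: dict,
    donors: Sequence[str],
    alpha_grid: Sequence[float] = (0.5,),
    doublet_margin: float = 2.0,
    min_calls: int = 3,
    eps: float = 0.01,
    droplet_id: str = "",
) -> DemuxAssignment:
    """Best singlet/doublet assignment for one droplet."""
    if len(donors) < 1:
        raise ValueError("need at least one candidate donor")
    n_calls = int((pileup["n_ref"] + pileup["n_alt"]).sum()) if len(pileup) else 0
    if n_calls < min_calls:
        return DemuxAssignment(droplet_id, "ambiguous", (), {}, 0.0, n_calls)
    lls: dict = {}
    for m in donors:
        lls[(m,)] = assignment_loglik(pileup, m, m, 0.0, posteriors, eps)
    for m1, m2 in combinations(donors, 2):
        best = -np.inf
        for a in alpha_grid:
            best = max(best, assignment_loglik(pileup, m1, m2, a, posteriors, eps))
        lls[(m1, m2)] = best
    singlets = {k: v for k, v in lls.items() if len(k) == 1}
    doublets = {k: v for k, v in lls.items() if len(k) == 2}
    best_singlet = max(singlets, key=singlets.get)
    if doublets:
        best_doublet = max(doublets, key=doublets.get)
        if doublets[best_doublet] - singlets[best_singlet] >= doublet_margin:
            ordered = sorted(lls.values(), reverse=True)
            margin = ordered[0] - ordered[1] if len(ordered) > 1 else 0.0
            return DemuxAssignment(droplet_id, "doublet", best_doublet, lls, float(margin), n_calls)
    ordered = sorted(lls.values(), reverse=True)
    margin = ordered[0] - ordered[1] if len(ordered) > 1 else 0.0
    return DemuxAssignment(droplet_id, "singlet", best_singlet, lls, float(margin), n_calls)


def demux_library(
    cells: pd.DataFrame,
    library_id: str,
    pileups: pd.DataFrame,
    genotypes: pd.DataFrame,
    multiplex_map: dict[str, list[str]],
    alpha_grid: Sequence[float] = (0.5,),
    doublet_margin: float = 2.0,
    min_calls: int = 3,
    eps: float = 0.01,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Annotate every droplet of a multiplexed library with donor or doublet flag.

    Returns (updated cell table, per-droplet assignment frame mirroring a
    ".best"-style schema).  Doublets are marked filtered with reason
    "demux_doublet"; ambiguous droplets with reason "demux_ambiguous".
    """
    if library_id not in multiplex_map:
        raise KeyError(f"library {library_id} not in multiplexing map")
    donors = multiplex_map[library_id]
    if len(donors) < 2:
        raise ValueError(f"library {library_id} is not multiplexed (needs >= 2 donors)")
    posteriors = genotype_posteriors(genotypes[donors])
    lib_pile = pileups[pileups["library_id"] == library_id]
    grouped = {bc: g for bc, g in lib_pile.groupby("barcode_id")}
    mask_lib = cells["library_id"] == library_id
    rows = []
    assignments = {}
    empty = pd.DataFrame(columns=["variant_id", "n_ref", "n_alt"])
    for bc in cells.loc[mask_lib, "barcode_id"]:
        pile = grouped.get(bc, empty)
        a = assign_droplet(pile, posteriors, donors, alpha_grid, doublet_margin, min_calls, eps, bc)
        assignments[bc] = a
        rows.append(
            {"library_id": library_id, "barcode_id": bc, "type": a.best_type,
             "donors": "+".join(a.best_donors), "margin": a.margin, "n_calls": a.n_calls}
        )
    out = cells.copy()
    bcs = out.loc[mask_lib, "barcode_id"]
    types = np.array([assignments[b].best_type for b in bcs])
    out.loc[mask_lib, "donor_id"] = [
        assignments[b].best_donors[0] if assignments[b].best_type == "singlet" else None
        for b in bcs
    ]
    out.loc[mask_lib, "doublet"] = out.loc[mask_lib, "doublet"] | (types == "doublet")
    dbl_mask = np.zeros(len(out), dtype=bool)
    dbl_mask[np.flatnonzero(mask_lib)] = types == "doublet"
    out = flag_cells(out, dbl_mask, "demux_doublet")
    amb_mask = np.zeros(len(out), dtype=bool)
    amb_mask[np.flatnonzero(mask_lib)] = types == "ambiguous"
    out = flag_cells(out, amb_mask, "demux_ambiguous")
    return out, pd.DataFrame(rows)
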