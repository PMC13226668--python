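"""Synthetic islet cohort generator with full ground truth.

Generates everything the downstream stages assume: negative-binomial UMI
counts with cell-type marker structure, planted T2D beta-cell DEGs,
multiplicative ambient ("soup") contamination at per-cell fraction rho,
empty droplets, cross-cell doublets, multiplexed genotype pileups with
base-call error, donor-group differences in beta-cell composition and HbA1c,
and evidence tables for the concordance prioritizer.  Every emitted droplet,
gene and evidence row carries a ground-truth record so parameter-recovery
tests need no external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io_cohort import (
    CohortBundle,
    CountsMatrix,
    DonorRecord,
    GlycemicState,
    new_cell_table,
)

STATES = ("ND", "PD", "T2D")

# Group HbA1c means follow the cohort description (T2D 7.6, PD 5.9, ND 5.2);
# the within-group spreads keep draws inside the prediabetes band rule.
HBA1C_MEANS = {"ND": 5.2, "PD": 5.9, "T2D": 7.6}
HBA1C_SDS = {"ND": 0.3, "PD": 0.2, "T2D": 0.3}

# beta-cell composition means per state (fractions); ND/T2D from the reported
# group means 55.2 / 42.2 %, PD from 57.2 %.
BETA_FRACTION_MEANS = {"ND": 0.552, "PD": 0.572, "T2D": 0.422}

CELL_TYPES = ("beta", "alpha", "delta", "gamma", "acinar", "ductal")
MARKERS = {
    "beta": "INS",
    "alpha": "GCG",
    "delta": "SST",
    "gamma": "PPY",
    "acinar": "REG1B",
    "ductal": "KRT19",
}
# Share of the non-beta mass given to each remaining type.
NONBETA_WEIGHTS = {"alpha": 0.55, "delta": 0.15, "gamma": 0.10, "acinar": 0.12, "ductal": 0.08}

N_MITO_GENES = 10
MITO_MASS = 0.05  # profile mass reserved for MT- genes => pMT around 5 %


def _default_deg_table() -> pd.DataFrame:
    """20 planted T2D-vs-ND beta-cell DEGs at |log2FC| = 1 (half up, half down)."""
    rows = []
    for i in range(10):
        rows.append({"gene": f"DEGUP{i:02d}", "cell_type": "beta", "state": "T2D", "log2fc": 1.0})
        rows.append({"gene": f"DEGDN{i:02d}", "cell_type": "beta", "state": "T2D", "log2fc": -1.0})
    return pd.DataFrame(rows)


@dataclass
class SimulationConfig:
    seed: int = 0
    n_donors: tuple[int, int, int] = (2, 2, 2)  # ND, PD, T2D
    cells_per_donor: int = 500
    n_genes: int = 2000
    nb_dispersion: float = 0.3
    libsize_log_mean: float = 9.2  # median ~ 10k UMIs
    libsize_log_sd: float = 0.35
    exocrine_libsize_factor: float = 0.4  # acinar/ductal libraries are shallower
    marker_boost: float = 300.0
    program_genes_per_type: int = 25
    program_boost: float = 8.0
    composition_concentration: float = 20.0  # Dirichlet strength; beta sd ~ 11 %
    planted_deg_table: pd.DataFrame = field(default_factory=_default_deg_table)
    # contamination: per (library, cell type) mean rho ~ Beta(a, b) with mean
    # a/(a+b) = 0.08; per-cell rho scatters tightly around its type mean.
    rho_beta_a: float = 2.0
    rho_beta_b: float = 23.0
    rho_within_type_conc: float = 200.0
    n_empty_droplets: int = 80_000
    empty_total_mean: float = 6.0
    doublet_rate: float = 0.1
    n_variants: int = 100
    allele_freq_range: tuple[float, float] = (0.1, 0.9)
    reads_per_variant: float = 1.0
    base_error: float = 0.01
    donors_per_library: int = 2
    # evidence planting: how many planted DEGs per concordance class
    n_concordant: int = 4
    n_discordant: int = 3
    n_mixed: int = 2

    def validate(self) -> None:
        if not 0 <= self.doublet_rate < 1:
            raise ValueError("doublet_rate must be in [0, 1)")
        if not 0 < self.base_error <= 0.5:
            raise ValueError("base_error must be in (0, 0.5]")
        if len(self.planted_deg_table) and not np.isfinite(
            self.planted_deg_table["log2fc"].astype(float)
        ).all():
            raise ValueError("planted log2FC must be finite")
        for s in STATES:
            if not 0 <= BETA_FRACTION_MEANS[s] <= 1:
                raise ValueError("beta fraction means must lie in [0,1]")


@dataclass
class GroundTruth:
    droplets: pd.DataFrame  # library_id, barcode_id, kind, donor_id(s), cell_type, rho, doublet
    genes: pd.DataFrame  # gene, is_deg, cell_type, state, log2fc
    soup: dict[str, np.ndarray]  # per-library true soup profile
    concordance: pd.DataFrame  # gene, true_class
    gene_ids: list[str]


# ---------------------------------------------------------------------------
# donors


def simulate_donor_metadata(cfg: SimulationConfig) -> list[DonorRecord]:
    """Draw donor records; HbA1c per state around the group means, age/BMI shared."""
    rng = np.random.default_rng(cfg.seed)
    donors: list[DonorRecord] = []
    i = 0
    for state, n in zip(STATES, cfg.n_donors):
        for _ in range(n):
            hba1c = float(np.clip(rng.normal(HBA1C_MEANS[state], HBA1C_SDS[state]), 3.5, 15.0))
            donors.append(
                DonorRecord(
                    donor_id=f"D{i:02d}",
                    state=GlycemicState(state),
                    hba1c=round(hba1c, 2),
                    age=round(float(rng.normal(52, 10)), 1),
                    bmi=round(float(rng.normal(30, 5)), 1),
                    sex="F" if rng.random() < 0.4 else "M",
                    ancestry=str(rng.choice(["EUR", "HISP", "AFR"], p=[0.5, 0.35, 0.15])),
                    chemistry="V3",  # set per library during count simulation
                )
            )
            i += 1
    return donors


# ---------------------------------------------------------------------------
# expression profiles


def build_gene_universe(cfg: SimulationConfig, rng: np.random.Generator):
    """Gene ids plus per-type expression weight vectors (markers, programs, mito mass)."""
    n = cfg.n_genes
    deg_genes = list(cfg.planted_deg_table["gene"])
    special = list(MARKERS.values()) + [f"MT-{i+1}" for i in range(N_MITO_GENES)] + deg_genes
    n_generic = n - len(special)
    per_type = min(cfg.program_genes_per_type, n_generic // len(CELL_TYPES))
    if per_type < 1:
        raise ValueError("n_genes too small for the configured structure")
    gene_ids = special + [f"G{i:04d}" for i in range(n_generic)]

    base = rng.lognormal(mean=0.0, sigma=1.0, size=n)
    mito_idx = np.array([gene_ids.index(f"MT-{i+1}") for i in range(N_MITO_GENES)])

    profiles: dict[str, np.ndarray] = {}
    generic_start = len(special)
    prog_slots = rng.permutation(np.arange(generic_start, n))
    marker_idx = {t: gene_ids.index(MARKERS[t]) for t in CELL_TYPES}
    prog_idx = {
        t: prog_slots[t_i * per_type : (t_i + 1) * per_type]
        for t_i, t in enumerate(CELL_TYPES)
    }
    for t in CELL_TYPES:
        w = base.copy()
        # markers and program genes are near-structural zeros outside their
        # own type — marker genes are cell-type-restricted in real islets
        for other in CELL_TYPES:
            if other == t:
                continue
            w[marker_idx[other]] *= 1e-3
            w[prog_idx[other]] *= 0.05
        w[marker_idx[t]] = cfg.marker_boost * np.median(base)
        w[prog_idx[t]] *= cfg.program_boost
        # planted DEG genes live at a moderate baseline in beta cells
        for g in deg_genes:
            w[gene_ids.index(g)] = 4.0 * np.median(base)
        # fix the mitochondrial mass share
        w[mito_idx] = 0.0
        w = w / w.sum() * (1.0 - MITO_MASS)
        mito_w = rng.dirichlet(np.full(N_MITO_GENES, 5.0)) * MITO_MASS
        w[mito_idx] = mito_w
        profiles[t] = w
    return gene_ids, profiles


def _state_profiles(
    cfg: SimulationConfig, gene_ids: list[str], profiles: dict[str, np.ndarray]
) -> dict[tuple[str, str], np.ndarray]:
    """Per (cell type, state) probability vectors with planted DEG multipliers."""
    out: dict[tuple[str, str], np.ndarray] = {}
    gi = {g: i for i, g in enumerate(gene_ids)}
    for t in CELL_TYPES:
        for s in STATES:
            w = profiles[t].copy()
            sub = cfg.planted_deg_table
            hits = sub[(sub["cell_type"] == t) & (sub["state"] == s)]
            for _, row in hits.iterrows():
                w[gi[row["gene"]]] *= 2.0 ** row["log2fc"]
            out[(t, s)] = w / w.sum()
    return out


# ---------------------------------------------------------------------------
# true counts


def simulate_true_counts(
    cfg: SimulationConfig, donors: list[DonorRecord]
) -> tuple[dict[str, CountsMatrix], GroundTruth]:
    """Per-library true (uncontaminated) counts with per-droplet truth records.

    Donors are packed ``donors_per_library`` per library (multiplexed, V3);
    a trailing singleton library is V2.  Cell types are drawn per donor from
    a Dirichlet whose beta-cell mean follows the donor's glycemic state.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed + 1)
    gene_ids, profiles = build_gene_universe(cfg, rng)
    state_prof = _state_profiles(cfg, gene_ids, profiles)

    libraries: dict[str, CountsMatrix] = {}
    truth_rows = []
    k = cfg.donors_per_library
    groups = [donors[i : i + k] for i in range(0, len(donors), k)]
    size = 1.0 / cfg.nb_dispersion
    exo = {"acinar", "ductal"}
    for li, group in enumerate(groups):
        lib = f"L{li:02d}"
        chem = "V3" if len(group) >= 2 else "V2"
        for d in group:
            d.chemistry = chem
        cols = []
        for d in group:
            beta_mean = BETA_FRACTION_MEANS[d.state.value]
            alpha_vec = np.array(
                [beta_mean] + [(1 - beta_mean) * NONBETA_WEIGHTS[t] for t in CELL_TYPES[1:]]
            )
            comp = rng.dirichlet(alpha_vec * cfg.composition_concentration)
            types = rng.choice(len(CELL_TYPES), size=cfg.cells_per_donor, p=comp)
            libsizes = rng.lognormal(cfg.libsize_log_mean, cfg.libsize_log_sd, cfg.cells_per_donor)
            for ci in range(cfg.cells_per_donor):
                t = CELL_TYPES[types[ci]]
                n_c = libsizes[ci] * (cfg.exocrine_libsize_factor if t in exo else 1.0)
                mu = n_c * state_prof[(t, d.state.value)]
                counts = rng.negative_binomial(size, size / (size + mu))
                cols.append(counts)
                truth_rows.append(
                    {
                        "library_id": lib,
                        "barcode_id": f"{lib}-BC{len(cols)-1:05d}",
                        "kind": "cell",
                        "donor_id": d.donor_id,
                        "donor_ids": (d.donor_id,),
                        "cell_type": t,
                        "rho": 0.0,
                        "doublet": False,
                    }
                )
        mat = sp.csc_matrix(np.column_stack(cols).astype(np.int64))
        barcodes = [f"{lib}-BC{i:05d}" for i in range(mat.shape[1])]
        libraries[lib] = CountsMatrix(mat, list(gene_ids), barcodes, library_id=lib)

    truth = GroundTruth(
        droplets=pd.DataFrame(truth_rows),
        genes=_gene_truth(cfg, gene_ids),
        soup={},
        concordance=pd.DataFrame(),
        gene_ids=list(gene_ids),
    )
    return libraries, truth


def _gene_truth(cfg: SimulationConfig, gene_ids: list[str]) -> pd.DataFrame:
    sub = cfg.planted_deg_table.set_index("gene")
    rows = []
    for g in gene_ids:
        if g in sub.index:
            r = sub.loc[g]
            rows.append(
                {"gene": g, "is_deg": True, "cell_type": r["cell_type"], "state": r["state"],
                 "log2fc": float(r["log2fc"])}
            )
        else:
            rows.append({"gene": g, "is_deg": False, "cell_type": None, "state": None, "log2fc": 0.0})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# ambient soup + empty droplets


def _soup_multinomials(
    rng: np.random.Generator, totals: np.ndarray, soup: np.ndarray
) -> sp.csc_matrix:
    """Sparse gene x droplet matrix of multinomial soup draws (vectorized by total)."""
    n_genes = len(soup)
    n = len(totals)
    rows_acc, cols_acc, data_acc = [], [], []
    for tot in np.unique(totals):
        if tot == 0:
            continue
        idx = np.flatnonzero(totals == tot)
        draws = rng.multinomial(int(tot), soup, size=len(idx))  # droplets x genes
        r, c = np.nonzero(draws)
        rows_acc.append(c)
        cols_acc.append(idx[r])
        data_acc.append(draws[r, c])
    if not rows_acc:
        return sp.csc_matrix((n_genes, n), dtype=np.int64)
    return sp.csc_matrix(
        (np.concatenate(data_acc), (np.concatenate(rows_acc), np.concatenate(cols_acc))),
        shape=(n_genes, n), dtype=np.int64,
    )


def apply_ambient_and_empties(
    true_counts: dict[str, CountsMatrix], cfg: SimulationConfig, truth: GroundTruth
) -> dict[str, CountsMatrix]:
    """Replace a Binomial(N_c, rho_c) share of each cell's UMIs with soup draws.

    The soup profile is the cohort-wide count-weighted gene frequency of the
    true counts, so the globally most expressed (hormone) genes dominate it.
    Contamination means vary by (library, cell type) — rho_type ~ Beta(a, b)
    with mean 0.08 — and per-cell rho scatters tightly around the type mean,
    matching the observation that contamination load tracks cell identity.
    Pure-soup empty droplets with small totals (most below the empty
    threshold of 10) are appended per library, stored sparsely.
    """
    rng = np.random.default_rng(cfg.seed + 2)
    pooled = None
    for m in true_counts.values():
        s = np.asarray(m.values.sum(axis=1)).ravel()
        pooled = s if pooled is None else pooled + s
    soup = pooled / pooled.sum()

    cell_type_of = {
        (r.library_id, r.barcode_id): r.cell_type
        for r in truth.droplets.itertuples()
    }
    out: dict[str, CountsMatrix] = {}
    rho_map: dict[tuple[str, str], float] = {}
    kappa = cfg.rho_within_type_conc
    for lib, m in true_counts.items():
        dense = np.asarray(m.values.todense())
        n_cells = dense.shape[1]
        type_mean = {
            t: float(rng.beta(cfg.rho_beta_a, cfg.rho_beta_b)) for t in CELL_TYPES
        }
        cols = []
        for c in range(n_cells):
            t = cell_type_of[(lib, m.barcode_ids[c])]
            mu = type_mean[t]
            if 1e-8 < mu < 1 - 1e-8:
                rho_c = float(rng.beta(mu * kappa, (1 - mu) * kappa))
            else:  # degenerate type mean (rho ~ 0 or ~ 1 exactly)
                rho_c = float(np.clip(mu, 0.0, 1.0))
            counts = dense[:, c]
            total = int(counts.sum())
            k = rng.binomial(total, rho_c) if total > 0 else 0
            if k > 0:
                removed = rng.multivariate_hypergeometric(counts.astype(np.int64), k)
                counts = counts - removed + rng.multinomial(k, soup)
            cols.append(counts)
            rho_map[(lib, m.barcode_ids[c])] = rho_c
        cell_block = sp.csc_matrix(np.column_stack(cols).astype(np.int64))
        empty_totals = rng.poisson(cfg.empty_total_mean, size=cfg.n_empty_droplets)
        empty_block = _soup_multinomials(rng, empty_totals, soup)
        mat = sp.hstack([cell_block, empty_block]).tocsc()
        empty_bcs = [f"{lib}-EMPTY{e:05d}" for e in range(cfg.n_empty_droplets)]
        out[lib] = CountsMatrix(mat, m.gene_ids, list(m.barcode_ids) + empty_bcs, library_id=lib)
        truth.soup[lib] = soup.copy()

    d = truth.droplets
    d["rho"] = [rho_map.get((l, b), 0.0) for l, b in zip(d["library_id"], d["barcode_id"])]
    empties = []
    for lib in true_counts:
        for e in range(cfg.n_empty_droplets):
            empties.append(
                {"library_id": lib, "barcode_id": f"{lib}-EMPTY{e:05d}", "kind": "empty",
                 "donor_id": None, "donor_ids": (), "cell_type": None, "rho": 1.0, "doublet": False}
            )
    truth.droplets = pd.concat([d, pd.DataFrame(empties)], ignore_index=True)
    return out


# ---------------------------------------------------------------------------
# doublets


def inject_doublets(
    raw: dict[str, CountsMatrix], cfg: SimulationConfig, truth: GroundTruth
) -> dict[str, CountsMatrix]:
    """Merge pairs of cell droplets into summed doublet droplets.

    A Binomial(n_cells, doublet_rate) number of doublets is formed per
    library; each consumes two uniformly chosen distinct cells (cross-donor
    pairs arise naturally in multiplexed libraries) and the pair's UMI
    multiset is conserved in the merged droplet.
    """
    if cfg.doublet_rate >= 1:
        raise ValueError("doublet_rate must be < 1")
    rng = np.random.default_rng(cfg.seed + 3)
    out: dict[str, CountsMatrix] = {}
    info = {
        (r.library_id, r.barcode_id): r for r in truth.droplets.itertuples()
    }
    new_rows = []
    drop_keys = set()
    for lib, m in raw.items():
        kinds = np.array([info[(lib, bc)].kind for bc in m.barcode_ids])
        cell_idx = np.flatnonzero(kinds == "cell")
        n_d = rng.binomial(len(cell_idx), cfg.doublet_rate) if cfg.doublet_rate > 0 else 0
        n_d = min(n_d, len(cell_idx) // 2)
        pairs = rng.choice(cell_idx, size=2 * n_d, replace=False).reshape(n_d, 2)
        csc = m.values.tocsc()
        keep = np.ones(csc.shape[1], dtype=bool)
        new_bcs = []
        dbl_cols = []
        for pi, (a, b) in enumerate(pairs):
            keep[a] = keep[b] = False
            col = (csc[:, a] + csc[:, b]).toarray().ravel()
            dbl_cols.append(col)
            bc = f"{lib}-DBL{pi:05d}"
            new_bcs.append(bc)
            ra = info[(lib, m.barcode_ids[a])]
            rb = info[(lib, m.barcode_ids[b])]
            ta = csc[:, a].sum()
            tb = csc[:, b].sum()
            w = ta / (ta + tb) if ta + tb > 0 else 0.5
            new_rows.append(
                {"library_id": lib, "barcode_id": bc, "kind": "doublet",
                 "donor_id": None, "donor_ids": (ra.donor_id, rb.donor_id),
                 "cell_type": f"{ra.cell_type}+{rb.cell_type}",
                 "rho": w * ra.rho + (1 - w) * rb.rho, "doublet": True}
            )
            drop_keys.add((lib, m.barcode_ids[a]))
            drop_keys.add((lib, m.barcode_ids[b]))
        keep_idx = np.flatnonzero(keep)
        blocks = [csc[:, keep_idx]]
        if dbl_cols:
            blocks.append(sp.csc_matrix(np.column_stack(dbl_cols).astype(np.int64)))
        mat = sp.hstack(blocks).tocsc()
        bcs = [m.barcode_ids[i] for i in keep_idx] + new_bcs
        out[lib] = CountsMatrix(mat, m.gene_ids, bcs, library_id=lib)
    mask = [
        (l, b) not in drop_keys
        for l, b in zip(truth.droplets["library_id"], truth.droplets["barcode_id"])
    ]
    truth.droplets = pd.concat(
        [truth.droplets[mask], pd.DataFrame(new_rows)], ignore_index=True
    )
    return out


# ---------------------------------------------------------------------------
# genotypes and pileups


def simulate_genotype_pileups(
    cfg: SimulationConfig,
    donors: list[DonorRecord],
    truth: GroundTruth,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Biallelic variants under Hardy-Weinberg plus per-droplet allele pileups.

    Returns (genotype table: variant x donor dosage, pileup table with per
    (droplet, variant) REF/ALT call counts).  Doublet droplets draw each read
    from a 50/50 donor mixture; every call flips with probability
    ``base_error``.
    """
    if cfg.n_variants < 1:
        raise ValueError("n_variants must be >= 1")
    rng = np.random.default_rng(cfg.seed + 4)
    lo, hi = cfg.allele_freq_range
    freqs = rng.uniform(lo, hi, size=cfg.n_variants)
    var_ids = [f"rs{i:05d}" for i in range(cfg.n_variants)]
    geno = {}
    for d in donors:
        a1 = rng.random(cfg.n_variants) < freqs
        a2 = rng.random(cfg.n_variants) < freqs
        geno[d.donor_id] = (a1.astype(int) + a2.astype(int))
    geno_df = pd.DataFrame(geno, index=var_ids)
    geno_df.index.name = "variant_id"

    rows = []
    cells = truth.droplets[truth.droplets["kind"].isin(["cell", "doublet"])]
    for _, r in cells.iterrows():
        donors_here = list(r["donor_ids"])
        n_reads = rng.poisson(cfg.reads_per_variant, size=cfg.n_variants)
        for v in np.flatnonzero(n_reads):
            n_alt = 0
            for _ in range(n_reads[v]):
                src = donors_here[0] if len(donors_here) == 1 else donors_here[int(rng.random() < 0.5)]
                g = geno_df.iloc[v][src]
                alt = rng.random() < g / 2.0
                if rng.random() < cfg.base_error:
                    alt = not alt
                n_alt += int(alt)
            rows.append(
                {"library_id": r["library_id"], "barcode_id": r["barcode_id"],
                 "variant_id": var_ids[v], "n_ref": int(n_reads[v]) - n_alt, "n_alt": n_alt}
            )
    return geno_df, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# evidence tables for the prioritizer


@dataclass
class EvidenceTables:
    gwas: pd.DataFrame
    ld: pd.DataFrame
    eqtl: pd.DataFrame
    deg: pd.DataFrame
    protein: pd.DataFrame
    mouse_ko: pd.DataFrame


def simulate_evidence_tables(
    cfg: SimulationConfig, deg_truth: pd.DataFrame, seed_offset: int = 5
) -> tuple[EvidenceTables, pd.DataFrame]:
    """Construct GWAS/LD/eQTL/protein/mouse-KO evidence with planted classes.

    Concordant genes get one variant whose risk-allele-oriented eQTL Z sign
    matches the DEG sign (direction string ++++/----); discordant genes the
    opposite; mixed genes two independent signals (LD r2 below the proxy
    threshold) with opposite oriented signs.
    """
    rng = np.random.default_rng(cfg.seed + seed_offset)
    degs = deg_truth[deg_truth["is_deg"]].reset_index(drop=True)
    genes = list(degs["gene"])
    need = cfg.n_concordant + cfg.n_discordant + cfg.n_mixed
    if len(genes) < need:
        raise ValueError("not enough planted DEGs to build evidence tables")
    chosen = list(rng.choice(genes, size=need, replace=False))
    classes = (
        [("concordant", g) for g in chosen[: cfg.n_concordant]]
        + [("discordant", g) for g in chosen[cfg.n_concordant : cfg.n_concordant + cfg.n_discordant]]
        + [("mixed", g) for g in chosen[cfg.n_concordant + cfg.n_discordant :]]
    )
    sign_of = dict(zip(degs["gene"], np.sign(degs["log2fc"]).astype(int)))
    bases = ["A", "C", "G", "T"]
    gwas_rows, eqtl_rows, ld_rows, truth_rows = [], [], [], []
    vi = 0

    def new_variant(locus: str):
        nonlocal vi
        risk, other = rng.choice(bases, size=2, replace=False)
        vid = f"rsE{vi:04d}"
        vi += 1
        gwas_rows.append(
            {"variant_id": vid, "risk_allele": risk, "other_allele": other,
             "odds_ratio": round(float(rng.uniform(1.03, 1.2)), 3),
             "p": 5e-9, "study": "meta", "locus": locus}
        )
        return vid, risk, other

    for cls, g in classes:
        deg_sign = sign_of[g]
        if cls in ("concordant", "discordant"):
            vid, risk, other = new_variant(f"locus_{g}")
            z_sign = deg_sign if cls == "concordant" else -deg_sign
            # half the records are reported on the non-risk allele to exercise
            # allele orientation: flip both the allele and the Z sign.
            flip = rng.random() < 0.5
            eff = other if flip else risk
            z = z_sign * float(rng.uniform(2.0, 3.0)) * (-1 if flip else 1)
            eqtl_rows.append(
                {"variant_id": vid, "effect_allele": eff, "gene": g, "z": round(z, 2),
                 "p": 0.01, "cohort_directions": "++++" if z > 0 else "----"}
            )
            # an LD proxy above threshold inheriting the orientation
            pvid = f"rsE{vi:04d}"
            vi += 1
            ld_rows.append({"v1": vid, "v2": pvid, "r2": 0.85, "phase_risk_allele": risk})
        else:  # mixed: two independent signals with opposite oriented signs
            vid1, risk1, _ = new_variant(f"locusA_{g}")
            vid2, risk2, _ = new_variant(f"locusB_{g}")
            ld_rows.append({"v1": vid1, "v2": vid2, "r2": 0.28, "phase_risk_allele": ""})
            for vid, risk, s in ((vid1, risk1, deg_sign), (vid2, risk2, -deg_sign)):
                z = s * float(rng.uniform(2.0, 3.0))
                eqtl_rows.append(
                    {"variant_id": vid, "effect_allele": risk, "gene": g, "z": round(z, 2),
                     "p": 0.02, "cohort_directions": "++++" if z > 0 else "----"}
                )
        truth_rows.append({"gene": g, "true_class": cls})

    deg_table = degs[["gene", "log2fc"]].copy()
    deg_table["fdr"] = 0.001
    protein = pd.DataFrame(
        [
            {"gene": g, "log2fc": sign_of[g] * 0.5, "p": 0.01}
            for cls, g in classes
            if cls == "concordant"
        ]
    )
    mouse = pd.DataFrame(
        [
            {
                "gene": g,
                "phenotype": "glucose tolerance",
                "direction": "impaired" if sign_of[g] < 0 else "improved",
            }
            for cls, g in classes
            if cls == "concordant"
        ]
    )
    tables = EvidenceTables(
        gwas=pd.DataFrame(gwas_rows),
        ld=pd.DataFrame(ld_rows),
        eqtl=pd.DataFrame(eqtl_rows),
        deg=deg_table,
        protein=protein,
        mouse_ko=mouse,
    )
    return tables, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# top-level assembly


@dataclass
class SyntheticCohort:
    bundle: CohortBundle
    truth: GroundTruth
    genotypes: pd.DataFrame
    pileups: pd.DataFrame
    evidence: EvidenceTables
    evidence_truth: pd.DataFrame
    config: SimulationConfig


def simulate_cohort(cfg: Optional[SimulationConfig] = None) -> SyntheticCohort:
    """Run the full generator and assemble a validated cohort bundle."""
    cfg = cfg or SimulationConfig()
    donors = simulate_donor_metadata(cfg)
    true_counts, truth = simulate_true_counts(cfg, donors)
    raw = apply_ambient_and_empties(true_counts, cfg, truth)
    raw = inject_doublets(raw, cfg, truth)
    genotypes, pileups = simulate_genotype_pileups(cfg, donors, truth)
    evidence, ev_truth = simulate_evidence_tables(cfg, truth.genes)
    truth.concordance = ev_truth

    # "filtered" matrices = raw minus empty droplets (cell-calling emulation)
    filtered: dict[str, CountsMatrix] = {}
    kind_of = {
        (r.library_id, r.barcode_id): r.kind for r in truth.droplets.itertuples()
    }
    cell_tables = []
    for lib, m in raw.items():
        keep = np.array([kind_of[(lib, bc)] != "empty" for bc in m.barcode_ids])
        idx = np.flatnonzero(keep)
        filtered[lib] = CountsMatrix(
            m.values[:, idx], m.gene_ids, [m.barcode_ids[i] for i in idx], library_id=lib
        )
        cell_tables.append(new_cell_table(filtered[lib].barcode_ids, lib))

    # donor -> library map
    mmap: dict[str, list[str]] = {}
    cells_only = truth.droplets[truth.droplets["kind"] == "cell"]
    for lib in raw:
        mmap[lib] = sorted(cells_only.loc[cells_only["library_id"] == lib, "donor_id"].unique())
    bundle = CohortBundle(
        raw=raw,
        filtered=filtered,
        cells=pd.concat(cell_tables, ignore_index=True),
        donors=donors,
        multiplex_map=mmap,
    )
    return SyntheticCohort(bundle, truth, genotypes, pileups, evidence, ev_truth, cfg)


# ---------------------------------------------------------------------------
# focused simulators used by the pseudobulk-DE and co-expression stages


def simulate_pseudobulk(
    n_per_state: dict[str, int],
    n_genes: int,
    planted: Optional[pd.DataFrame] = None,
    dispersion: float = 0.1,
    lib_size: float = 2e5,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Donor-level NB pseudobulk counts with optional planted state effects.

    ``planted`` columns: gene (integer index or name), state, log2fc.  Returns
    (counts genes x samples, design frame with state/chemistry/sex/ancestry/
    age/bmi columns).  Used for DE calibration and power checks where a full
    single-cell cohort would be wasteful.
    """
    rng = np.random.default_rng(seed)
    genes = [f"G{i:04d}" for i in range(n_genes)]
    base = rng.lognormal(1.0, 1.0, size=n_genes)
    base = base / base.sum()
    design_rows = []
    cols = {}
    size = 1.0 / dispersion
    i = 0
    for state, n in n_per_state.items():
        for _ in range(n):
            sid = f"S{i:03d}"
            w = base.copy()
            if planted is not None:
                hits = planted[planted["state"] == state]
                for _, r in hits.iterrows():
                    gi = genes.index(r["gene"]) if isinstance(r["gene"], str) else int(r["gene"])
                    w[gi] *= 2.0 ** r["log2fc"]
            mu = lib_size * w / w.sum() * float(rng.lognormal(0, 0.2))
            cols[sid] = rng.negative_binomial(size, size / (size + mu))
            design_rows.append(
                {"sample": sid, "state": state,
                 "chemistry": "V3" if rng.random() < 0.8 else "V2",
                 "sex": "F" if rng.random() < 0.4 else "M",
                 "ancestry": str(rng.choice(["EUR", "HISP"])),
                 "age": float(rng.normal(52, 10)), "bmi": float(rng.normal(30, 5))}
            )
            i += 1
    counts = pd.DataFrame(cols, index=genes)
    design = pd.DataFrame(design_rows).set_index("sample")
    return counts, design


def simulate_composition_cohort(
    n_per_state: dict[str, int] = None,
    cells_per_donor: int = 500,
    concentration: float = 20.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-donor realized beta-cell percentages plus HbA1c, no counts.

    Draws each donor's cell-type composition from the same Dirichlet model as
    the full generator (beta mean by state: ND 55.2 %, PD 57.2 %, T2D 42.2 %,
    sd ~ 11 %) and the realized fraction from a multinomial over
    ``cells_per_donor`` cells.  Used for composition-statistics replicates
    where simulating expression would be wasteful.
    """
    n_per_state = n_per_state or {"ND": 17, "T2D": 17}
    rng = np.random.default_rng(seed)
    rows = []
    i = 0
    for state, n in n_per_state.items():
        for _ in range(n):
            beta_mean = BETA_FRACTION_MEANS[state]
            alpha_vec = np.array(
                [beta_mean] + [(1 - beta_mean) * NONBETA_WEIGHTS[t] for t in CELL_TYPES[1:]]
            )
            comp = rng.dirichlet(alpha_vec * concentration)
            counts = rng.multinomial(cells_per_donor, comp)
            hba1c = float(rng.normal(HBA1C_MEANS[state], HBA1C_SDS[state]))
            rows.append(
                {"donor_id": f"D{i:02d}", "state": state, "hba1c": hba1c,
                 "beta_pct": 100.0 * counts[0] / cells_per_donor}
            )
            i += 1
    return pd.DataFrame(rows)


def simulate_coexpression_blocks(
    n_samples: int = 40,
    block_sizes: tuple[int, ...] = (120, 120, 120),
    n_noise: int = 200,
    within_cor: float = 0.8,
    seed: int = 0,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Sample x gene expression with planted correlated blocks plus noise genes.

    Returns (expression frame, true labels: 1..k for block genes, 0 for noise).
    """
    rng = np.random.default_rng(seed)
    cols = []
    labels = []
    for bi, size in enumerate(block_sizes):
        seed_profile = rng.normal(0, 1, n_samples)
        lam = np.sqrt(within_cor)
        noise_sd = np.sqrt(1 - within_cor)
        block = seed_profile[:, None] * lam + rng.normal(0, noise_sd, (n_samples, size))
        cols.append(block)
        labels += [bi + 1] * size
    cols.append(rng.normal(0, 1, (n_samples, n_noise)))
    labels += [0] * n_noise
    expr = np.concatenate(cols, axis=1)
    genes = [f"CX{i:04d}" for i in range(expr.shape[1])]
    return pd.DataFrame(expr, columns=genes), np.array(labels)
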