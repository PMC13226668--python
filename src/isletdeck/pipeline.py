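"""End-to-end orchestration: simulate/load -> decontaminate -> demultiplex ->
QC -> integrate/cluster -> doublet enrichment -> annotate -> pseudobulk DE ->
co-expression modules -> prioritize -> cohort statistics.

Every removal writes a machine-readable reason into the cell table; the run
report reconciles raw droplet counts against kept cells plus reasoned
removals (the audit identity) and records the thresholds and seed used.
"""

from __future__ import annotations

import json
import logging
import sys
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import cluster as cl
from . import cohort_stats as cs
from . import coexpr as cx
from . import decontam as dc
from . import demux as dx
from . import doublet_enrich as de
from . import prioritize as pz
from . import pseudobulk as pb
from . import qc
from .io_cohort import FloatMatrix
from .synthetic import SimulationConfig, SyntheticCohort, simulate_cohort

log = logging.getLogger("isletdeck")
if not log.handlers:
    h = logging.StreamHandler(sys.stderr)
    h.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    log.addHandler(h)
    log.setLevel(logging.INFO)


@dataclass
class RunConfig:
    seed: int = 0
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    qc_thresholds: qc.QCThresholds = field(default_factory=qc.QCThresholds)
    skip_demux: bool = False
    n_hvg: int = 500
    n_pcs: int = 30
    cluster_resolution: float = 1.0
    coexpr_top_genes: int = 300
    coexpr_min_module_size: int = 25
    coexpr_power: int = 12

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        sim = SimulationConfig(**raw.pop("simulation", {})) if "simulation" in raw else SimulationConfig()
        th = qc.QCThresholds(**raw.pop("qc_thresholds", {})) if "qc_thresholds" in raw else qc.QCThresholds()
        return cls(simulation=sim, qc_thresholds=th, **raw)


def _quick_clusters(norm: cl.NormalizedMatrix, n_hvg: int, n_pcs: int, seed: int) -> np.ndarray:
    """Per-library provisional clustering used for soup estimation and QC."""
    hvg = cl.select_hvg(norm, n=min(n_hvg, len(norm.gene_ids)))
    emb = cl.embed_pca(norm, hvg, n_pcs=min(n_pcs, 20))
    k = min(20, emb.coords.shape[0] - 1)
    return cl.snn_cluster(emb, k=k, resolution=0.5, seed=seed).labels


def run_pipeline(cfg: Optional[RunConfig] = None, cohort: Optional[SyntheticCohort] = None) -> dict:
    """Execute the full pipeline; returns the run report dictionary."""
    cfg = cfg or RunConfig()
    t0 = time.time()
    if cohort is None:
        sim_cfg = cfg.simulation
        if sim_cfg.seed != cfg.seed:
            sim_cfg.seed = cfg.seed
        log.info("stage simulate: generating synthetic cohort (seed=%d)", cfg.seed)
        cohort = simulate_cohort(sim_cfg)
    bundle = cohort.bundle
    truth = cohort.truth
    report: dict = {"seed": cfg.seed, "stages": {}, "thresholds": asdict(cfg.qc_thresholds)}

    # ---- decontamination ------------------------------------------------
    log.info("stage decontam: soup estimation and correction")
    corrected: dict[str, FloatMatrix] = {}
    lib_clusters: dict[str, np.ndarray] = {}
    for lib, raw in bundle.raw.items():
        soup = dc.estimate_soup_profile(raw, empty_threshold=10)
        filt = bundle.filtered[lib]
        norm = cl.lognormalize(filt)
        labels = _quick_clusters(norm, cfg.n_hvg, cfg.n_pcs, cfg.seed)
        lib_clusters[lib] = labels
        est = dc.estimate_contamination(filt, soup, labels)
        corrected[lib] = dc.correct_counts(filt, soup, est)
    assessment = dc.assess_decontamination(bundle.filtered, corrected)
    report["stages"]["decontam"] = {
        "libraries": len(corrected),
        "top_contaminant": assessment.table.nsmallest(1, "mean_rank")["gene"].iloc[0],
    }

    # ---- demultiplexing --------------------------------------------------
    cells = bundle.cells
    if not cfg.skip_demux:
        log.info("stage demux: genotype-likelihood donor assignment")
        for lib in bundle.raw:
            donors_here = bundle.multiplex_map[lib]
            if len(donors_here) < 2:
                # single-donor library: assign directly
                cells.loc[cells["library_id"] == lib, "donor_id"] = donors_here[0]
                continue
            cells, _ = dx.demux_library(
                cells, lib, cohort.pileups, cohort.genotypes, bundle.multiplex_map
            )
    else:
        truth_map = truth.droplets.set_index(["library_id", "barcode_id"])["donor_id"]
        cells["donor_id"] = [
            truth_map.get((l, b)) for l, b in zip(cells["library_id"], cells["barcode_id"])
        ]
    report["stages"]["demux"] = {
        "doublets_flagged": int(cells["doublet"].sum()),
        "assigned": int(cells["donor_id"].notna().sum()),
    }

    # ---- per-library QC ---------------------------------------------------
    log.info("stage qc: metrics, preliminary filter, doublet consensus")
    th = cfg.qc_thresholds
    mito_genes = [g for g in bundle.raw[next(iter(bundle.raw))].gene_ids if g.startswith("MT-")]
    consensus_flags = np.zeros(len(cells), dtype=bool)
    for lib, filt in bundle.filtered.items():
        cells = qc.compute_cell_metrics(filt, cells, mito_genes)
    cells = qc.preliminary_filter(cells, th)
    for lib, filt in bundle.filtered.items():
        sel = np.flatnonzero((cells["library_id"] == lib).to_numpy())
        norm = cl.lognormalize(corrected[lib])
        dense = np.asarray(norm.values.todense()).T
        raw_dense = np.asarray(filt.values.todense()).T
        scores = qc.simulated_doublet_scores(dense, th, seed=cfg.seed, counts=raw_dense)
        consensus_flags[sel] = qc.consensus_doublets(scores)
    report["stages"]["qc"] = {
        "prelim_filtered": int(cells["filtered"].sum()),
        "consensus_doublets": int(consensus_flags.sum()),
    }

    # ---- integration + clustering + annotation ---------------------------
    log.info("stage cluster: integration, SNN clustering, annotation")
    libs = sorted(bundle.filtered)
    gene_ids = bundle.filtered[libs[0]].gene_ids
    import scipy.sparse as sp

    merged = sp.hstack([corrected[l].values for l in libs]).tocsc()
    barcodes = [f"{l}::{b}" for l in libs for b in bundle.filtered[l].barcode_ids]
    merged_m = FloatMatrix(merged, gene_ids, barcodes, library_id="merged")
    norm_all = cl.lognormalize(merged_m)
    hvg = cl.select_hvg(norm_all, n=min(cfg.n_hvg, len(gene_ids)))
    emb = cl.embed_pca(norm_all, hvg, n_pcs=cfg.n_pcs)
    donor_map = bundle.donor_frame().set_index("donor_id")
    order = pd.concat(
        [cells[cells["library_id"] == l] for l in libs]
    ).reset_index()  # row order matching merged columns
    covs = pd.DataFrame(
        {
            "sex": [
                donor_map.loc[d, "sex"] if pd.notna(d) and d in donor_map.index else "unknown"
                for d in order["donor_id"]
            ],
            "chemistry": [
                donor_map.loc[d, "chemistry"] if pd.notna(d) and d in donor_map.index else "unknown"
                for d in order["donor_id"]
            ],
        }
    )
    emb = cl.covariate_align(emb, covs, seed=cfg.seed)
    clustering = cl.snn_cluster(emb, k=20, resolution=cfg.cluster_resolution, seed=cfg.seed)
    ann = cl.annotate_clusters(clustering, norm_all)
    type_of = dict(zip(ann["cluster"], ann["cell_type"]))
    order_index = order["index"].to_numpy()
    cells.loc[order_index, "cluster"] = clustering.labels
    cells.loc[order_index, "cell_type"] = [type_of[c] for c in clustering.labels]
    report["stages"]["cluster"] = {
        "n_clusters": int(clustering.labels.max() + 1),
        "annotated_types": sorted(set(type_of.values())),
    }

    # ---- adaptive per-library thresholds ----------------------------------
    for lib in bundle.filtered:
        sel = cells["library_id"] == lib
        cutoff, trigger = qc.adaptive_nfea_threshold(cells[sel], th)
        if trigger is not None:
            log.info("library %s: relaxed nFEA cutoff %d (cluster %s)", lib, cutoff, trigger)
        cells = qc.flag_cells_nfea(cells, sel, cutoff)
    cells = qc.flag_high_pmt(cells, th)

    # ---- doublet enrichment ----------------------------------------------
    log.info("stage enrich: cluster doublet enrichment")
    cons_in_order = consensus_flags[order_index]
    enrich = de.doublet_enrichment_test(clustering.labels, cons_in_order)
    coexpr_flags = de.hormone_coexpression_flags(norm_all, clustering.labels)
    cells_in_order = cells.loc[order_index].reset_index(drop=True)
    cells_in_order, removed = de.remove_enriched_clusters(
        cells_in_order, clustering.labels, enrich, coexpr_flags, cons_in_order
    )
    cells_in_order.index = order_index
    cells.loc[order_index] = cells_in_order
    cells = qc.annotation_aware_filter(cells, th)
    report["stages"]["enrich"] = {
        "enriched_clusters_removed": [int(c) for c in removed],
    }

    # ---- pseudobulk DE ----------------------------------------------------
    log.info("stage de: pseudobulk NB-GLM differential expression")
    pbm = pb.aggregate_pseudobulk(cells, bundle.filtered, bundle.donor_frame())
    beta_cols = pbm.design[pbm.design["cell_type"] == "beta"].index
    de_result = None
    if len(beta_cols) >= 4 and pbm.design.loc[beta_cols, "state"].nunique() >= 2:
        beta_counts = pbm.counts[beta_cols]
        expressed = (beta_counts > 0).sum(axis=1) >= max(2, len(beta_cols) // 3)
        keep_genes = beta_counts.index[expressed][: 400]
        design_b = pbm.design.loc[beta_cols]
        covars = [c for c in pb.DEFAULT_COVARIATES
                  if c in design_b.columns and design_b[c].astype(str).nunique() > 1]
        # drop covariates aliased with the state factor (tiny cohorts)
        while covars:
            try:
                pb._design_matrix(design_b, "state", covars)
                break
            except ValueError as exc:
                blamed = next(
                    (c for c in covars if c in str(exc)), covars[-1]
                )
                covars.remove(blamed)
                log.warning("dropping aliased covariate %s", blamed)
        try:
            fit = pb.fit_nb_glm(
                beta_counts.loc[keep_genes], design_b, covariates=covars,
                lib_sizes=beta_counts.sum(axis=0),
            )
            if {"ND", "T2D"} <= set(fit.levels):
                de_result = pb.test_contrast(fit, "T2D", "ND")
        except ValueError as exc:
            log.warning("DE stage skipped: %s", exc)
    degs = pb.call_degs(de_result) if de_result is not None else {"up": [], "down": []}
    report["stages"]["de"] = {
        "n_pseudobulk_samples": int(pbm.counts.shape[1]),
        "n_up": len(degs["up"]),
        "n_down": len(degs["down"]),
    }

    # ---- co-expression modules -------------------------------------------
    log.info("stage modules: signed co-expression network")
    module_report = {"n_modules": 0}
    if len(beta_cols) >= 6:
        logcpm = pb.cpm_log(pbm.counts[beta_cols])
        expressed = (pbm.counts[beta_cols] > 0).sum(axis=1) > max(2, len(beta_cols) // 2)
        var_rank = logcpm[expressed].var(axis=1).nlargest(cfg.coexpr_top_genes)
        expr = logcpm.loc[var_rank.index]
        design_b = pbm.design.loc[beta_cols]
        cov_cols = [c for c in ("sex", "chemistry", "ancestry", "age_scaled", "bmi_scaled")
                    if c in design_b.columns and design_b[c].astype(str).nunique() > 1]
        if cov_cols and len(beta_cols) > len(cov_cols) + 2:
            expr = cx.residualize_covariates(expr, design_b[cov_cols])
        net_cfg = cx.NetworkConfig(
            chosen_power=cfg.coexpr_power, min_module_size=cfg.coexpr_min_module_size
        )
        adj = cx.signed_adjacency(expr, net_cfg.chosen_power)
        tom = cx.tom_similarity(adj)
        part = cx.detect_modules(expr, 1.0 - tom, net_cfg)
        module_report["n_modules"] = int(len(set(part.labels) - {0}))
        if module_report["n_modules"] and len(part.eigengenes.columns) >= 4:
            traits = pd.DataFrame(
                {
                    "hba1c": [float(donor_map.loc[s.split("|")[0], "hba1c"]) for s in beta_cols],
                    "t2d": [
                        1.0 if donor_map.loc[s.split("|")[0], "state"] == "T2D" else 0.0
                        for s in beta_cols
                    ],
                },
                index=beta_cols,
            )
            mt = cx.module_trait_correlation(part.eigengenes, traits)
            module_report["n_significant_trait_pairs"] = int(mt["significant"].sum())
    report["stages"]["modules"] = module_report

    # ---- prioritization ----------------------------------------------------
    log.info("stage prioritize: GWAS/eQTL concordance triage")
    ev = cohort.evidence
    cand = pz.prioritize_genes(ev.gwas, ev.ld, ev.eqtl, ev.deg, ev.protein, ev.mouse_ko)
    report["stages"]["prioritize"] = {
        "n_classified": int(len(cand)),
        "n_candidates": int(cand["candidate"].sum()) if len(cand) else 0,
    }

    # ---- cohort statistics --------------------------------------------------
    log.info("stage stats: composition and similarity statistics")
    donors_df = bundle.donor_frame()
    comp = cs.composition_table(cells, donors_df)
    stats_report = {"similarity": cs.state_similarity_matrix(donors_df).to_dict()}
    if len(comp):
        trait = donors_df.set_index("donor_id")["hba1c"].astype(float)
        corr = cs.composition_trait_correlation(comp, trait)
        if len(corr):
            stats_report["beta_hba1c_rho"] = float(
                corr.set_index("cell_type")["rho"].get("beta", np.nan)
            )
    report["stages"]["stats"] = stats_report

    # ---- audit ---------------------------------------------------------------
    n_raw = sum(m.n_droplets for m in bundle.raw.values())
    n_filtered = sum(m.n_droplets for m in bundle.filtered.values())
    kept = int((~cells["filtered"]).sum())
    reason_counts: dict[str, int] = {"not_cell_called": n_raw - n_filtered}
    for lst in cells.loc[cells["filtered"], "reasons"]:
        primary = lst[0] if lst else "unspecified"
        reason_counts[primary] = reason_counts.get(primary, 0) + 1
    report["audit"] = {
        "raw_droplets": n_raw,
        "kept_cells": kept,
        "removals_by_reason": reason_counts,
        "reconciled": n_raw == kept + sum(reason_counts.values()),
    }
    report["runtime_seconds"] = round(time.time() - t0, 2)
    log.info("pipeline complete in %.1fs (kept %d cells)", report["runtime_seconds"], kept)
    return report


def write_report(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, default=str))
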