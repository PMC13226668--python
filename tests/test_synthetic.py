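"""Generator contracts: determinism, conservation laws, ground-truth completeness,
and the statistical structure downstream stages rely on."""

import numpy as np
import pandas as pd
import pytest

from isletdeck.io_cohort import validate_cohort
from isletdeck.synthetic import (
    HBA1C_MEANS,
    SimulationConfig,
    apply_ambient_and_empties,
    inject_doublets,
    simulate_cohort,
    simulate_donor_metadata,
    simulate_evidence_tables,
    simulate_genotype_pileups,
    simulate_pseudobulk,
    simulate_true_counts,
)


class TestDonorMetadata:
    def test_t2d_hba1c_near_group_mean(self):
        cfg = SimulationConfig(seed=0, n_donors=(17, 14, 17))
        donors = simulate_donor_metadata(cfg)
        t2d = [d.hba1c for d in donors if d.state.value == "T2D"]
        assert len(t2d) == 17
        assert abs(np.mean(t2d) - HBA1C_MEANS["T2D"]) < 0.3

    def test_single_donor(self):
        donors = simulate_donor_metadata(SimulationConfig(n_donors=(1, 0, 0)))
        assert len(donors) == 1 and donors[0].state.value == "ND"

    def test_determinism(self):
        cfg = SimulationConfig(seed=5, n_donors=(3, 3, 3))
        a = simulate_donor_metadata(cfg)
        b = simulate_donor_metadata(cfg)
        assert [(d.donor_id, d.hba1c, d.age, d.sex) for d in a] == [
            (d.donor_id, d.hba1c, d.age, d.sex) for d in b
        ]


class TestTrueCounts:
    def test_null_model_states_equal(self):
        """With no planted effects the beta-cell profile is state-independent."""
        cfg = SimulationConfig(
            seed=1, n_donors=(2, 0, 2), cells_per_donor=150, n_genes=300,
            planted_deg_table=pd.DataFrame(columns=["gene", "cell_type", "state", "log2fc"]),
        )
        donors = simulate_donor_metadata(cfg)
        counts, truth = simulate_true_counts(cfg, donors)
        d = truth.droplets
        means = {}
        for state in ("ND", "T2D"):
            dn = [x.donor_id for x in donors if x.state.value == state]
            sel = d[(d["cell_type"] == "beta") & d["donor_id"].isin(dn)]
            cols = []
            for lib, grp in sel.groupby("library_id"):
                m = counts[lib]
                pos = {b: i for i, b in enumerate(m.barcode_ids)}
                idx = [pos[b] for b in grp["barcode_id"]]
                cols.append(np.asarray(m.values[:, idx].sum(axis=1)).ravel())
            pooled = np.sum(cols, axis=0)
            means[state] = pooled / pooled.sum()
        # total-variation distance between state profiles is sampling noise only
        assert 0.5 * np.abs(means["ND"] - means["T2D"]).sum() < 0.05

    def test_beta_fraction_direction(self, mid_cohort):
        d = mid_cohort.truth.droplets
        cells = d[d["kind"] == "cell"]
        donors = {x.donor_id: x.state.value for x in mid_cohort.bundle.donors}
        fracs = {"ND": [], "T2D": []}
        for donor, grp in cells.groupby("donor_id"):
            st = donors[donor]
            if st in fracs:
                fracs[st].append((grp["cell_type"] == "beta").mean())
        assert np.mean(fracs["T2D"]) < np.mean(fracs["ND"])

    def test_poisson_limit_variance_mean(self):
        """NB dispersion -> 0 gives variance/mean -> 1 (checked at 1e4 draws)."""
        rng = np.random.default_rng(0)
        mu, size = 5.0, 1.0 / 1e-8
        draws = rng.negative_binomial(size, size / (size + mu), size=10_000)
        ratio = draws.var() / draws.mean()
        assert abs(ratio - 1.0) < 0.05


class TestAmbient:
    def _tiny(self, **kw):
        cfg = SimulationConfig(
            seed=3, n_donors=(1, 0, 0), cells_per_donor=80, n_genes=200,
            n_empty_droplets=100, donors_per_library=1, **kw,
        )
        donors = simulate_donor_metadata(cfg)
        counts, truth = simulate_true_counts(cfg, donors)
        return cfg, counts, truth

    def test_rho_zero_identity(self):
        cfg, counts, truth = self._tiny(rho_beta_a=1e-9, rho_beta_b=1.0)
        raw = apply_ambient_and_empties(counts, cfg, truth)
        lib = next(iter(counts))
        n = counts[lib].n_droplets
        assert (raw[lib].values[:, :n] != counts[lib].values).nnz == 0

    def test_rho_one_pure_soup(self):
        cfg, counts, truth = self._tiny(rho_beta_a=1.0, rho_beta_b=1e-9)
        raw = apply_ambient_and_empties(counts, cfg, truth)
        lib = next(iter(counts))
        n = counts[lib].n_droplets
        pooled = np.asarray(raw[lib].values[:, :n].sum(axis=1)).ravel().astype(float)
        freq = pooled / pooled.sum()
        soup = truth.soup[lib]
        assert 0.5 * np.abs(freq - soup).sum() < 0.05  # multinomial error only

    def test_top_soup_genes_are_most_expressed(self, small_cohort):
        truth = small_cohort.truth
        lib = next(iter(truth.soup))
        top_soup = set(np.argsort(truth.soup[lib])[::-1][:5])
        gene_ids = truth.gene_ids
        assert gene_ids.index("INS") in top_soup


class TestDoublets:
    def _tiny_raw(self, rate):
        cfg = SimulationConfig(
            seed=4, n_donors=(1, 0, 1), cells_per_donor=100, n_genes=150,
            n_empty_droplets=50, doublet_rate=rate,
        )
        donors = simulate_donor_metadata(cfg)
        counts, truth = simulate_true_counts(cfg, donors)
        raw = apply_ambient_and_empties(counts, cfg, truth)
        return cfg, raw, truth

    def test_rate_zero_unchanged(self):
        cfg, raw, truth = self._tiny_raw(0.0)
        before = {l: m.values.sum() for l, m in raw.items()}
        out = inject_doublets(raw, cfg, truth)
        assert {l: m.values.sum() for l, m in out.items()} == before
        assert not truth.droplets["doublet"].any()

    def test_umi_conservation(self):
        """Total UMIs are conserved: doublets are sums of their two parents."""
        cfg, raw, truth = self._tiny_raw(0.1)
        before = {l: int(m.values.sum()) for l, m in raw.items()}
        out = inject_doublets(raw, cfg, truth)
        assert {l: int(m.values.sum()) for l, m in out.items()} == before

    def test_expected_doublet_count(self):
        cfg = SimulationConfig(
            seed=5, n_donors=(1, 0, 1), cells_per_donor=500, n_genes=100,
            n_empty_droplets=20, doublet_rate=0.1,
        )
        donors = simulate_donor_metadata(cfg)
        counts, truth = simulate_true_counts(cfg, donors)
        raw = apply_ambient_and_empties(counts, cfg, truth)
        inject_doublets(raw, cfg, truth)
        n_dbl = int(truth.droplets["doublet"].sum())
        # Binomial(1000, 0.1): ~100 +/- 5 sd
        assert 55 <= n_dbl <= 145

    def test_rate_one_rejected(self):
        cfg, raw, truth = self._tiny_raw(0.0)
        cfg.doublet_rate = 1.0
        with pytest.raises(ValueError):
            inject_doublets(raw, cfg, truth)


class TestGenotypePileups:
    def test_zero_error_calls_match_genotype(self):
        cfg = SimulationConfig(
            seed=6, n_donors=(1, 0, 1), cells_per_donor=40, n_genes=100,
            n_empty_droplets=20, n_variants=30, base_error=1e-12, doublet_rate=0.0,
        )
        c = simulate_cohort(cfg)
        truth_map = c.truth.droplets.set_index(["library_id", "barcode_id"])
        geno = c.genotypes
        for _, row in c.pileups.iterrows():
            donor = truth_map.loc[(row["library_id"], row["barcode_id"]), "donor_id"]
            g = geno.loc[row["variant_id"], donor]
            if g == 0:
                assert row["n_alt"] == 0
            elif g == 2:
                assert row["n_ref"] == 0

    def test_empirical_error_rate_matches_epsilon(self):
        """Homozygous sites: observed mismatch frequency ~= base_error."""
        cfg = SimulationConfig(
            seed=7, n_donors=(2, 0, 2), cells_per_donor=150, n_genes=100,
            n_empty_droplets=20, n_variants=120, base_error=0.01, doublet_rate=0.0,
            reads_per_variant=2.0,
        )
        c = simulate_cohort(cfg)
        truth_map = c.truth.droplets.set_index(["library_id", "barcode_id"])["donor_id"]
        geno = c.genotypes
        mism = tot = 0
        for _, row in c.pileups.iterrows():
            donor = truth_map.loc[(row["library_id"], row["barcode_id"])]
            g = geno.loc[row["variant_id"], donor]
            n = row["n_ref"] + row["n_alt"]
            if g == 0:
                mism += row["n_alt"]
                tot += n
            elif g == 2:
                mism += row["n_ref"]
                tot += n
        assert tot > 50_000
        assert abs(mism / tot - 0.01) < 0.003


class TestEvidence:
    def test_planted_classes_constructed(self, small_cohort):
        ev, truth = small_cohort.evidence, small_cohort.evidence_truth
        mixed = truth[truth["true_class"] == "mixed"]["gene"]
        for g in mixed:
            zs = ev.eqtl[ev.eqtl["gene"] == g]["z"]
            assert len(zs) == 2 and np.sign(zs.iloc[0]) != np.sign(zs.iloc[1])

    def test_mixed_signals_below_ld_threshold(self, small_cohort):
        ev = small_cohort.evidence
        mixed_pairs = ev.ld[ev.ld["r2"] < 0.80]
        assert len(mixed_pairs) >= 1
        assert (mixed_pairs["r2"] == 0.28).all()


class TestCohortAssembly:
    def test_determinism_byte_identical(self, small_cfg):
        a = simulate_cohort(small_cfg)
        b = simulate_cohort(small_cfg)
        for lib in a.bundle.raw:
            assert (a.bundle.raw[lib].values != b.bundle.raw[lib].values).nnz == 0
        pd.testing.assert_frame_equal(a.truth.droplets, b.truth.droplets)
        pd.testing.assert_frame_equal(a.genotypes, b.genotypes)

    def test_truth_completeness(self, small_cohort):
        truth_keys = set(
            zip(small_cohort.truth.droplets["library_id"], small_cohort.truth.droplets["barcode_id"])
        )
        for lib, m in small_cohort.bundle.raw.items():
            for bc in m.barcode_ids:
                assert (lib, bc) in truth_keys
        assert set(small_cohort.truth.genes["gene"]) == set(small_cohort.truth.gene_ids)

    def test_bundle_passes_validation(self, small_cohort):
        assert validate_cohort(small_cohort.bundle) == []


class TestPseudobulkSimulator:
    def test_planted_fold_change_realized(self):
        planted = pd.DataFrame([{"gene": "G0000", "state": "T2D", "log2fc": 2.0}])
        counts, design = simulate_pseudobulk(
            {"ND": 20, "T2D": 20}, 50, planted=planted, seed=1
        )
        cpm = counts / counts.sum(axis=0) * 1e6
        nd = cpm.loc["G0000", design.index[design["state"] == "ND"]].mean()
        t2d = cpm.loc["G0000", design.index[design["state"] == "T2D"]].mean()
        assert 2.5 < np.log2(t2d / nd) + 1.5 and np.log2(t2d / nd) > 1.0
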