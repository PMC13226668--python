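"""Normalization, HVG selection, PCA, covariate alignment, SNN clustering,
marker annotation, and one-vs-rest marker tests."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from isletdeck import cluster as cl
from conftest import make_counts


class TestLogNormalize:
    def test_hand_value(self):
        """n=5 of N=10 at sf=10000 -> ln(5001)."""
        m = make_counts(np.array([[5], [5]]))
        nm = cl.lognormalize(m)
        assert nm.values[0, 0] == pytest.approx(np.log(5001.0), abs=1e-9)

    def test_zero_count_zero(self):
        m = make_counts(np.array([[0], [7]]))
        assert cl.lognormalize(m).values[0, 0] == 0.0

    def test_depth_invariance(self):
        """Doubling a cell's counts leaves its normalized vector unchanged."""
        a = cl.lognormalize(make_counts(np.array([[3], [7]])))
        b = cl.lognormalize(make_counts(np.array([[6], [14]])))
        assert np.allclose(a.values.toarray(), b.values.toarray())

    def test_zero_total_cell_maps_to_zeros(self):
        m = make_counts(np.array([[0, 3], [0, 1]]))
        nm = cl.lognormalize(m)
        assert nm.values[:, 0].nnz == 0


class TestHVG:
    def test_constant_genes_never_selected(self):
        """Zero-variance (normalized) genes lose to any varying gene."""
        import scipy.sparse as sp

        rng = np.random.default_rng(0)
        vals = np.vstack([np.full((5, 50), 2.0), rng.uniform(0, 3, (45, 50))])
        nm = cl.NormalizedMatrix(
            sp.csr_matrix(vals), [f"g{i}" for i in range(50)], [f"c{i}" for i in range(50)]
        )
        hvg = cl.select_hvg(nm, n=45)
        assert {f"g{i}" for i in range(5)}.isdisjoint(hvg)

    def test_planted_hvg_recovered(self, small_cohort):
        """Marker/program genes drive cell-to-cell variance and should dominate."""
        lib = next(iter(small_cohort.bundle.filtered))
        nm = cl.lognormalize(small_cohort.bundle.filtered[lib])
        hvg = set(cl.select_hvg(nm, n=100))
        markers = {"INS", "GCG", "SST", "PPY", "REG1B", "KRT19"}
        assert len(markers & hvg) >= 5

    def test_n_equal_gene_count(self):
        m = make_counts(np.arange(12).reshape(3, 4))
        nm = cl.lognormalize(m)
        assert set(cl.select_hvg(nm, n=3)) == set(nm.gene_ids)

    def test_n_too_large_rejected(self):
        nm = cl.lognormalize(make_counts(np.eye(3, dtype=int)))
        with pytest.raises(ValueError):
            cl.select_hvg(nm, n=10)


class TestPCA:
    def test_rank_one_data(self):
        """Cells on a line in (normalized) gene space: PC1 explains ~100 %."""
        import scipy.sparse as sp

        s = np.linspace(-1, 1, 30)
        vals = 3.0 + np.outer(np.array([1.0, -2.0, 0.5]), s)  # genes x cells, rank 1
        nm = cl.NormalizedMatrix(
            sp.csr_matrix(vals), ["g0", "g1", "g2"], [f"c{i}" for i in range(30)]
        )
        emb = cl.embed_pca(nm, nm.gene_ids, n_pcs=3)
        assert emb.explained_variance_ratio[0] > 0.999

    def test_explained_variance_nonincreasing(self, small_cohort):
        lib = next(iter(small_cohort.bundle.filtered))
        nm = cl.lognormalize(small_cohort.bundle.filtered[lib])
        hvg = cl.select_hvg(nm, n=50)
        emb = cl.embed_pca(nm, hvg, n_pcs=10)
        assert np.all(np.diff(emb.explained_variance_ratio) <= 1e-12)

    def test_full_rank_reconstruction(self):
        rng = np.random.default_rng(1)
        arr = rng.integers(0, 40, (6, 20))
        nm = cl.lognormalize(make_counts(arr))
        x = np.asarray(nm.values.todense()).T
        mu, sd = x.mean(0), x.std(0)
        sd[sd == 0] = 1
        xs = (x - mu) / sd
        emb = cl.embed_pca(nm, nm.gene_ids, n_pcs=6)
        # completeness, rotation/sign-free: the coordinate Gram matrix
        # reproduces the scaled data's Gram matrix exactly
        assert np.allclose(emb.coords @ emb.coords.T, xs @ xs.T, atol=1e-8)


class TestCovariateAlign:
    def _embedding(self, coords):
        return cl.Embedding(coords, np.ones(coords.shape[1]), [], [f"c{i}" for i in range(len(coords))])

    def test_uniform_covariate_noop(self):
        rng = np.random.default_rng(2)
        coords = rng.normal(size=(80, 5))
        cov = pd.DataFrame({"chem": ["V3"] * 80})
        out = cl.covariate_align(self._embedding(coords.copy()), cov, seed=0)
        assert np.allclose(out.coords, coords, atol=1e-6)

    def test_planted_offset_removed(self):
        """A chemistry shift on PC1 shrinks >= 90 % after alignment."""
        rng = np.random.default_rng(3)
        coords = rng.normal(size=(200, 4))
        labels = np.array(["V2"] * 100 + ["V3"] * 100)
        coords[labels == "V2", 0] += 5.0
        cov = pd.DataFrame({"chem": labels})
        out = cl.covariate_align(self._embedding(coords.copy()), cov, seed=0)
        before = abs(coords[labels == "V2"].mean(0)[0] - coords[labels == "V3"].mean(0)[0])
        after = abs(
            out.coords[labels == "V2"].mean(0)[0] - out.coords[labels == "V3"].mean(0)[0]
        )
        assert after <= 0.1 * before

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(4)
        coords = rng.normal(size=(100, 4))
        cov = pd.DataFrame({"sex": rng.choice(["F", "M"], 100)})
        a = cl.covariate_align(self._embedding(coords.copy()), cov, seed=5)
        b = cl.covariate_align(self._embedding(coords.copy()), cov, seed=5)
        assert np.array_equal(a.coords, b.coords)


class TestSNNCluster:
    def _blobs(self, n=150, d=10, sep=8.0, seed=0):
        rng = np.random.default_rng(seed)
        a = rng.normal(0, 1, (n, d))
        b = rng.normal(0, 1, (n, d))
        b[:, 0] += sep
        coords = np.vstack([a, b])
        truth = np.array([0] * n + [1] * n)
        return coords, truth

    def test_two_blobs_ari_one(self):
        coords, truth = self._blobs()
        emb = cl.Embedding(coords, np.ones(10), [], [str(i) for i in range(len(coords))])
        c = cl.snn_cluster(emb, k=20, resolution=1.0, seed=0)
        assert adjusted_rand_score(truth, c.labels) == 1.0

    def test_resolution_to_zero_single_cluster(self):
        """On a connected graph, resolution -> 0 merges everything."""
        rng = np.random.default_rng(7)
        coords = rng.normal(0, 1, (200, 10))  # one blob: connected SNN graph
        emb = cl.Embedding(coords, np.ones(10), [], [str(i) for i in range(len(coords))])
        c = cl.snn_cluster(emb, k=20, resolution=1e-4, seed=0)
        assert c.labels.max() == 0

    def test_permutation_stability(self):
        coords, truth = self._blobs(seed=5)
        rng = np.random.default_rng(6)
        perm = rng.permutation(len(coords))
        emb1 = cl.Embedding(coords, np.ones(10), [], [str(i) for i in range(len(coords))])
        emb2 = cl.Embedding(coords[perm], np.ones(10), [], [str(i) for i in range(len(coords))])
        c1 = cl.snn_cluster(emb1, seed=0)
        c2 = cl.snn_cluster(emb2, seed=0)
        assert adjusted_rand_score(c1.labels[perm], c2.labels) == 1.0

    def test_k_too_large_rejected(self):
        emb = cl.Embedding(np.zeros((5, 2)), np.ones(2), [], list("abcde"))
        with pytest.raises(ValueError):
            cl.snn_cluster(emb, k=5)


class TestAnnotate:
    def test_planted_types_recovered(self, small_cohort):
        """Cluster-majority annotation recovers every planted type present."""
        lib = "L00"
        filt = small_cohort.bundle.filtered[lib]
        nm = cl.lognormalize(filt)
        hvg = cl.select_hvg(nm, n=200)
        emb = cl.embed_pca(nm, hvg, n_pcs=20)
        c = cl.snn_cluster(emb, k=20, resolution=1.0, seed=0)
        ann = cl.annotate_clusters(c, nm)
        d = small_cohort.truth.droplets.set_index(["library_id", "barcode_id"])
        true_types = np.array([str(d.loc[(lib, b), "cell_type"]) for b in filt.barcode_ids])
        type_of = dict(zip(ann["cluster"], ann["cell_type"]))
        singlet = np.array(["+" not in t for t in true_types])
        pred = np.array([type_of[l] for l in c.labels])
        acc = (pred[singlet] == true_types[singlet]).mean()
        assert acc >= 0.95

    def test_multi_hormone_flag(self):
        """A cluster high in both INS and SST is flagged doublet-suspect."""
        rng = np.random.default_rng(0)
        base = rng.integers(0, 3, (4, 90))
        arr = np.vstack([base, np.zeros((2, 90), dtype=int)])
        genes = ["g0", "g1", "g2", "g3", "INS", "SST"]
        arr[4, :30] = 50  # cluster 0: INS only
        arr[5, 30:60] = 50  # cluster 1: SST only
        arr[4, 60:] = 50  # cluster 2: both
        arr[5, 60:] = 50
        nm = cl.lognormalize(make_counts(arr, genes=genes))
        labels = np.repeat([0, 1, 2], 30)
        c = cl.Clustering(labels, 1.0, 20, 0, 0.0)
        panel = {"beta": "INS", "delta": "SST"}
        ann = cl.annotate_clusters(c, nm, panel=panel, z_min=0.5)
        assert bool(ann.loc[ann["cluster"] == 2, "multi_hormone"].iloc[0])
        assert not bool(ann.loc[ann["cluster"] == 0, "multi_hormone"].iloc[0])

    def test_empty_panel_rejected(self, small_cohort):
        lib = "L00"
        nm = cl.lognormalize(small_cohort.bundle.filtered[lib])
        c = cl.Clustering(np.zeros(nm.values.shape[1], dtype=int), 1.0, 20, 0, 0.0)
        with pytest.raises(ValueError):
            cl.annotate_clusters(c, nm, panel={})


class TestMarkerDE:
    def _dataset(self, n_per=120, planted_lfc=0.0, seed=0):
        rng = np.random.default_rng(seed)
        n = 2 * n_per
        labels = np.array([0] * n_per + [1] * n_per)
        arr = rng.poisson(5.0, size=(20, n))
        if planted_lfc:
            arr[0, labels == 1] = rng.poisson(5.0 * 2**planted_lfc, n_per)
        return make_counts(arr), labels

    def test_null_gene_not_reported(self):
        m, labels = self._dataset()
        nm = cl.lognormalize(m)
        res = cl.marker_de(nm, labels, target=1, family="logistic")
        assert not res["significant"].any()

    def test_planted_marker_detected(self):
        m, labels = self._dataset(planted_lfc=2.0, seed=1)
        nm = cl.lognormalize(m)
        res = cl.marker_de(nm, labels, target=1, family="logistic").set_index("gene")
        assert res.loc["g0", "fdr"] <= 0.01
        assert res.loc["g0", "log2fc"] > 0.25

    def test_negbinom_detects_planted(self):
        m, labels = self._dataset(planted_lfc=2.0, seed=2)
        nm = cl.lognormalize(m)
        res = cl.marker_de(
            nm, labels, target=1, family="negbinom", counts=m
        ).set_index("gene")
        assert res.loc["g0", "fdr"] <= 0.01

    def test_logistic_lrt_matches_direct_mle_oracle(self):
        """Tiny 2-gene instance: LRT equals direct likelihood maximization."""
        from scipy.optimize import minimize

        rng = np.random.default_rng(3)
        m, labels = self._dataset(n_per=40, planted_lfc=1.0, seed=3)
        nm = cl.lognormalize(m)
        res = cl.marker_de(nm, labels, target=1, family="logistic", genes=["g0", "g1"])
        x = np.asarray(nm.values[0, :].todense()).ravel()
        y = (labels == 1).astype(float)

        def negll(beta, xmat):
            eta = xmat @ beta
            return -(y * eta - np.log1p(np.exp(eta))).sum()

        x_full = np.column_stack([np.ones_like(x), x])
        x_null = np.ones((len(x), 1))
        ll_full = -minimize(negll, np.zeros(2), args=(x_full,), method="BFGS").fun
        ll_null = -minimize(negll, np.zeros(1), args=(x_null,), method="BFGS").fun
        from scipy.stats import chi2

        p_oracle = chi2.sf(2 * (ll_full - ll_null), 1)
        assert abs(res.set_index("gene").loc["g0", "p"] - p_oracle) < 1e-6

    def test_type_i_error_bounded(self):
        """Null data: fraction of genes at FDR <= 1 % stays <= 2 %."""
        rng = np.random.default_rng(4)
        arr = rng.poisson(4.0, size=(500, 160))
        labels = np.array([0] * 80 + [1] * 80)
        nm = cl.lognormalize(make_counts(arr))
        res = cl.marker_de(nm, labels, target=1, family="logistic")
        assert (res["fdr"] <= 0.01).mean() <= 0.02

    def test_small_target_cluster_rejected(self):
        m, labels = self._dataset(n_per=30)
        nm = cl.lognormalize(m)
        with pytest.raises(ValueError):
            cl.marker_de(nm, labels, target=1, min_cells=100)
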