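"""Signed co-expression network: residualization, soft-threshold scan, TOM vs
brute-force oracle, module detection, eigengenes, module-trait correlation."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from isletdeck import coexpr as cx
from isletdeck.synthetic import simulate_coexpression_blocks


def random_expr(n_genes=40, n_samples=25, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        rng.normal(size=(n_genes, n_samples)),
        index=[f"g{i}" for i in range(n_genes)],
        columns=[f"s{i}" for i in range(n_samples)],
    )


class TestResidualize:
    def _cov(self, n, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(
            {"sex": rng.choice(["F", "M"], n), "age": rng.normal(50, 10, n)},
            index=[f"s{i}" for i in range(n)],
        )

    def test_orthogonal_covariates_noop(self):
        expr = random_expr()
        cov = self._cov(25)
        # regress out, then verify genes orthogonal to covariates are untouched
        x = pd.get_dummies(cov, drop_first=True).astype(float)
        x.insert(0, "i", 1.0)
        proj = x.to_numpy() @ np.linalg.lstsq(x.to_numpy(), expr.to_numpy().T, rcond=None)[0]
        pre_ortho = expr.copy()
        pre_ortho.iloc[:, :] = expr.to_numpy() - proj.T + expr.to_numpy().mean(1, keepdims=True) * 0
        out = cx.residualize_covariates(pre_ortho, cov)
        resid_again = cx.residualize_covariates(out, cov)
        assert np.allclose(out.to_numpy(), resid_again.to_numpy(), atol=1e-10)

    def test_planted_sex_offset_removed(self):
        expr = random_expr(seed=1)
        cov = self._cov(25, seed=1)
        shifted = expr.copy()
        shifted.loc["g0", (cov["sex"] == "F").to_numpy()] += 2.0
        out = cx.residualize_covariates(shifted, cov)
        f = out.loc["g0", (cov["sex"] == "F").to_numpy()].mean()
        m = out.loc["g0", (cov["sex"] == "M").to_numpy()].mean()
        assert abs(f - m) < 1e-8

    def test_residuals_orthogonal_to_design(self):
        expr = random_expr(seed=2)
        cov = self._cov(25, seed=2)
        out = cx.residualize_covariates(expr, cov)
        centered = out.to_numpy() - out.to_numpy().mean(axis=1, keepdims=True)
        x = pd.get_dummies(cov, drop_first=True).astype(float).to_numpy()
        xc = x - x.mean(axis=0)
        assert np.abs(centered @ xc).max() < 1e-8


class TestAdjacencyScan:
    def test_signed_map_range(self):
        expr = random_expr(seed=3)
        for t in (1, 6, 12):
            a = cx.signed_adjacency(expr, t)
            assert a.min() >= 0 and a.max() <= 1
            assert np.allclose(a, a.T)

    def test_power_monotonicity(self):
        """Raising the power never increases any off-diagonal weight."""
        expr = random_expr(seed=4)
        a1 = cx.signed_adjacency(expr, 2)
        a2 = cx.signed_adjacency(expr, 8)
        off = ~np.eye(len(a1), dtype=bool)
        assert np.all(a2[off] <= a1[off] + 1e-12)

    def test_scale_free_structure_scores_high(self):
        """A continuous hub spectrum (preferential-attachment-like weights)
        produces a high scale-free fit at some power."""
        rng = np.random.default_rng(5)
        n_s, n_g = 60, 500
        w = rng.uniform(0.05, 0.98, n_g)
        f = rng.normal(0, 1, n_s)
        x = w[:, None] * f[None, :] + np.sqrt(1 - w**2)[:, None] * rng.normal(
            0, 1, (n_g, n_s)
        )
        expr = pd.DataFrame(
            x, index=[f"g{i}" for i in range(n_g)], columns=[f"s{i}" for i in range(n_s)]
        )
        scan = cx.soft_threshold_scan(expr, grid=(2, 6, 12))
        assert scan["sft_r2"].max() > 0.8
        assert scan["mean_connectivity"].is_monotonic_decreasing

    def test_noise_low_fit_at_power_one(self):
        expr = random_expr(n_genes=120, n_samples=30, seed=6)
        scan = cx.soft_threshold_scan(expr, grid=(1,))
        assert scan.loc[0, "sft_r2"] < 0.5
        assert scan.loc[0, "mean_connectivity"] > 20

    def test_constant_gene_rejected_from_adjacency(self):
        expr = random_expr(seed=7)
        expr.iloc[0] = 1.0
        with pytest.raises(ValueError, match="constant"):
            cx.signed_adjacency(expr, 6)

    def test_too_few_genes_rejected(self):
        with pytest.raises(ValueError, match="30"):
            cx.soft_threshold_scan(random_expr(n_genes=10))


class TestTOM:
    def test_hand_evaluated_triangle(self):
        a = np.array([[0, 0.5, 0.5], [0.5, 0, 0], [0.5, 0, 0]])
        tom = cx.tom_similarity(a)
        # l_12 = 0, a_12 = .5, min(k)=0.5 -> (0+.5)/(.5+1-.5) = 0.5
        assert tom[0, 1] == pytest.approx(0.5)
        assert np.allclose(np.diag(tom), 1.0)

    def test_identical_neighborhood_maximal(self):
        a = np.array([[0, 1.0], [1.0, 0]])
        assert cx.tom_similarity(a)[0, 1] == pytest.approx(1.0)

    def test_matches_triple_loop_oracle(self):
        """Vectorized TOM equals the O(n^3) definition on random instances."""
        rng = np.random.default_rng(8)
        for _ in range(5):
            n = 20
            a = rng.uniform(0, 1, (n, n))
            a = (a + a.T) / 2
            np.fill_diagonal(a, 0)
            tom = cx.tom_similarity(a)
            k = a.sum(axis=1)
            for i in range(n):
                for j in range(n):
                    if i == j:
                        continue
                    l_ij = sum(a[i, u] * a[u, j] for u in range(n))
                    expect = (l_ij + a[i, j]) / (min(k[i], k[j]) + 1 - a[i, j])
                    assert abs(tom[i, j] - expect) < 1e-12

    def test_asymmetric_rejected(self):
        a = np.array([[0, 0.5], [0.4, 0]])
        with pytest.raises(ValueError, match="symmetric"):
            cx.tom_similarity(a)


class TestModules:
    def _detect(self, seed=9, **cfg_kw):
        expr_sg, labels = simulate_coexpression_blocks(seed=seed)
        expr = expr_sg.T
        cfg = cx.NetworkConfig(chosen_power=12, min_module_size=100, **cfg_kw)
        adj = cx.signed_adjacency(expr, cfg.chosen_power)
        tom = cx.tom_similarity(adj)
        return expr, labels, cx.detect_modules(expr, 1.0 - tom, cfg)

    def test_planted_blocks_recovered(self):
        _, labels, part = self._detect()
        ari = adjusted_rand_score(labels[labels > 0], part.labels[labels > 0])
        assert ari >= 0.9
        assert (part.labels[labels == 0] == 0).mean() >= 0.8  # noise to grey

    def test_grey_identity(self):
        _, _, part = self._detect()
        sizes = sum((part.labels == m).sum() for m in set(part.labels) - {0})
        assert sizes + (part.labels == 0).sum() == len(part.labels)

    def test_merge_cut_zero_no_merging(self):
        _, _, part0 = self._detect(merge_cut_height=0.0)
        _, _, part = self._detect()
        assert len(set(part0.labels) - {0}) >= len(set(part.labels) - {0})

    def test_near_identical_blocks_merged(self):
        """Two blocks driven by ~the same latent profile merge into one module."""
        rng = np.random.default_rng(10)
        n_s = 40
        seed_profile = rng.normal(0, 1, n_s)
        lam, sd = np.sqrt(0.85), np.sqrt(0.15)
        blocks = [
            seed_profile[:, None] * lam + rng.normal(0, sd, (n_s, 120)) for _ in range(2)
        ]
        noise = rng.normal(0, 1, (n_s, 150))
        expr = pd.DataFrame(
            np.concatenate(blocks + [noise], axis=1).T,
            index=[f"g{i}" for i in range(390)],
            columns=[f"s{i}" for i in range(n_s)],
        )
        cfg = cx.NetworkConfig(chosen_power=12, min_module_size=100)
        tom = cx.tom_similarity(cx.signed_adjacency(expr, 12))
        part = cx.detect_modules(expr, 1.0 - tom, cfg)
        block_labels = part.labels[:240]
        assigned = block_labels[block_labels > 0]
        assert len(set(assigned)) == 1

    def test_gene_permutation_stability(self):
        expr_sg, labels = simulate_coexpression_blocks(seed=11)
        expr = expr_sg.T
        rng = np.random.default_rng(12)
        perm = rng.permutation(len(expr))
        cfg = cx.NetworkConfig(chosen_power=12, min_module_size=100)
        tom1 = cx.tom_similarity(cx.signed_adjacency(expr, 12))
        p1 = cx.detect_modules(expr, 1.0 - tom1, cfg)
        expr_p = expr.iloc[perm]
        tom2 = cx.tom_similarity(cx.signed_adjacency(expr_p, 12))
        p2 = cx.detect_modules(expr_p, 1.0 - tom2, cfg)
        assert adjusted_rand_score(p1.labels[perm], p2.labels) == 1.0


class TestEigengene:
    def test_perfectly_correlated_module(self):
        rng = np.random.default_rng(13)
        profile = rng.normal(size=20)
        expr = pd.DataFrame(
            np.vstack([3 * profile + 1, -2 * profile, profile]),
            index=["g0", "g1", "g2"], columns=[f"s{i}" for i in range(20)],
        )
        eg = cx.module_eigengene(expr, np.array([1, 1, 1]))
        z = (profile - profile.mean()) / profile.std()
        e = eg.loc[1].to_numpy()
        cor = np.corrcoef(e, z)[0, 1]
        assert abs(abs(cor) - 1.0) < 1e-10

    def test_orientation_positive_with_module_mean(self):
        expr_sg, labels = simulate_coexpression_blocks(seed=14)
        expr = expr_sg.T
        eg = cx.module_eigengene(expr, labels)
        x = expr.to_numpy()
        for m in eg.index:
            sub = x[labels == m]
            z = (sub - sub.mean(1, keepdims=True)) / sub.std(1, keepdims=True)
            assert np.corrcoef(eg.loc[m], z.mean(0))[0, 1] >= 0

    def test_svd_optimality_vs_oracle(self):
        """Eigengene explains at least as much module variance as random unit vectors."""
        rng = np.random.default_rng(15)
        expr = pd.DataFrame(rng.normal(size=(30, 15)))
        labels = np.ones(30, dtype=int)
        eg = cx.module_eigengene(expr, labels).loc[1].to_numpy()
        sub = expr.to_numpy()
        z = (sub - sub.mean(1, keepdims=True)) / sub.std(1, keepdims=True)
        var_eig = ((z @ eg) ** 2).sum()
        for _ in range(50):
            v = rng.normal(size=15)
            v /= np.linalg.norm(v)
            assert ((z @ v) ** 2).sum() <= var_eig + 1e-9


class TestModuleTrait:
    def test_monotone_trait_rho_one(self):
        eg = pd.DataFrame({"s%d" % i: [float(i)] for i in range(12)}, index=[1])
        traits = pd.DataFrame(
            {"hba1c": np.exp(np.arange(12) / 3.0)}, index=eg.columns
        )
        out = cx.module_trait_correlation(eg, traits)
        assert out.loc[0, "rho"] == pytest.approx(1.0)

    def test_matches_rank_pearson_oracle(self):
        rng = np.random.default_rng(16)
        eg = pd.DataFrame(rng.normal(size=(2, 18)), index=[1, 2],
                          columns=[f"s{i}" for i in range(18)])
        traits = pd.DataFrame({"t": rng.normal(size=18)}, index=eg.columns)
        out = cx.module_trait_correlation(eg, traits).set_index("module")
        from scipy.stats import rankdata

        for m in (1, 2):
            r = np.corrcoef(rankdata(eg.loc[m]), rankdata(traits["t"]))[0, 1]
            assert abs(out.loc[m, "rho"] - r) < 1e-12

    def test_constant_trait_nan(self):
        eg = pd.DataFrame(np.random.default_rng(17).normal(size=(1, 10)), index=[1])
        traits = pd.DataFrame({"t": np.ones(10)}, index=eg.columns)
        out = cx.module_trait_correlation(eg, traits)
        assert np.isnan(out.loc[0, "rho"])
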