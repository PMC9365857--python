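import numpy as np
import pandas as pd
import pytest
from scipy.stats import t as t_dist

from tuftnet import coexpr


def block_expression(rng, n_samples=12, block_sizes=(50, 50), n_noise=100,
                     noise_sd=0.3):
    """Genes in a block share a latent sample profile plus noise."""
    cols, names = [], []
    for b, size in enumerate(block_sizes):
        latent = rng.normal(size=n_samples)
        for j in range(size):
            cols.append(latent + rng.normal(0, noise_sd, n_samples))
            names.append(f"b{b}_{j}")
    for j in range(n_noise):
        cols.append(rng.normal(size=n_samples))
        names.append(f"noise{j}")
    df = pd.DataFrame(np.column_stack(cols), columns=names)
    return (df - df.mean()) / df.std(ddof=1)


class TestSoftThreshold:
    def test_block_structure_saturates(self):
        """A heavy-tailed module-size spectrum (one large module, many small
        ones, plenty of unconnected genes) saturates the scale-free fit and
        the smallest passing power is chosen."""
        rng = np.random.default_rng(1)
        sizes = [40] + [12] * 4 + [5] * 20 + [2] * 50
        z = block_expression(rng, n_samples=25, block_sizes=tuple(sizes),
                             n_noise=250, noise_sd=0.3)
        beta, table = coexpr.pick_soft_threshold(z)
        passing = table[table.sft_r2 >= 0.85]
        assert len(passing)
        assert beta == passing["power"].iloc[0]

    def test_noise_uses_fallback(self, rng):
        z = block_expression(rng, n_samples=8, block_sizes=(), n_noise=60)
        beta, table = coexpr.pick_soft_threshold(z)
        if (table.sft_r2 >= 0.85).any():
            pytest.skip("chance saturation")
        assert beta == table.loc[table.sft_r2.idxmax(), "power"]

    def test_single_candidate_power(self, rng):
        z = block_expression(rng, block_sizes=(20,), n_noise=10)
        beta, _ = coexpr.pick_soft_threshold(z, powers=[6])
        assert beta == 6


class TestAdjacency:
    @pytest.mark.parametrize("cor,beta,expected", [
        (1.0, 7, 1.0),
        (-1.0, 3, 0.0),
        (0.0, 14, 0.5**14),
    ])
    def test_closed_form(self, cor, beta, expected):
        assert coexpr.adjacency_signed(np.array([[cor]]), beta)[0, 0] == \
            pytest.approx(expected)

    def test_monotone_decreasing_in_beta(self, rng):
        cor = np.clip(rng.uniform(-0.99, 0.99, size=(4, 4)), None, 0.99)
        a_low = coexpr.adjacency_signed(cor, 2)
        a_high = coexpr.adjacency_signed(cor, 10)
        assert np.all(a_high <= a_low + 1e-15)


def brute_force_tom(A):
    n = A.shape[0]
    k = A.sum(axis=1) - np.diag(A)
    out = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            l = sum(A[i, u] * A[u, j] for u in range(n) if u not in (i, j))
            out[i, j] = (l + A[i, j]) / (min(k[i], k[j]) + 1 - A[i, j])
    return out


class TestTOM:
    def test_two_gene_collapse(self):
        x = 0.37
        A = np.array([[1.0, x], [x, 1.0]])
        tom = coexpr.tom_matrix(A)
        assert tom[0, 1] == pytest.approx(x)

    def test_triangle_all_ones(self):
        A = np.ones((3, 3))
        tom = coexpr.tom_matrix(A)
        np.testing.assert_allclose(tom, 1.0)

    def test_matches_bruteforce(self, rng):
        for _ in range(20):
            n = rng.integers(5, 9)
            B = rng.uniform(0, 1, size=(n, n))
            A = (B + B.T) / 2
            np.fill_diagonal(A, 1.0)
            np.testing.assert_allclose(coexpr.tom_matrix(A), brute_force_tom(A),
                                       atol=1e-12)

    def test_asymmetric_input_rejected(self):
        A = np.array([[1.0, 0.2], [0.5, 1.0]])
        with pytest.raises(ValueError, match="symmetric"):
            coexpr.tom_matrix(A)


class TestDetectModules:
    def test_two_planted_blocks_recovered(self, rng):
        z = block_expression(rng, block_sizes=(50, 50), n_noise=100)
        net = coexpr.build_network(z)
        truth = [{f"b0_{j}" for j in range(50)}, {f"b1_{j}" for j in range(50)}]
        recovered = 0
        for t_set in truth:
            for m in net.modules.unique():
                if m == coexpr.UNASSIGNED:
                    continue
                genes = set(net.modules.index[net.modules == m])
                if len(genes & t_set) / len(genes | t_set) >= 0.8:
                    recovered += 1
                    break
        assert recovered == 2

    def test_single_block_single_module(self, rng):
        z = block_expression(rng, block_sizes=(80,), n_noise=0, noise_sd=0.2)
        net = coexpr.build_network(z)
        mods = [m for m in net.modules.unique() if m != coexpr.UNASSIGNED]
        assert len(mods) == 1

    def test_oversized_min_module_all_grey(self, rng):
        z = block_expression(rng, block_sizes=(20,), n_noise=0)
        cor = np.corrcoef(z.to_numpy().T)
        tom = coexpr.tom_matrix(coexpr.adjacency_signed(cor, 6))
        tom = pd.DataFrame(tom, index=z.columns, columns=z.columns)
        labels, eig, _ = coexpr.detect_modules(tom, z, min_module_size=50)
        assert (labels == coexpr.UNASSIGNED).all()
        assert eig.shape[1] == 0


class TestEigengenes:
    def test_identical_genes(self, rng):
        profile = rng.normal(size=8)
        z = pd.DataFrame({f"g{j}": profile for j in range(5)})
        z = (z - z.mean()) / z.std(ddof=1)
        eig = coexpr.module_eigengenes(z, pd.Series("m", index=z.columns))
        c = np.corrcoef(eig["m"], z["g0"])[0, 1]
        assert abs(c) == pytest.approx(1.0)
        assert c > 0  # orientation follows the average profile

    def test_sign_flip_invariance(self, rng):
        z = block_expression(rng, block_sizes=(6,), n_noise=0)
        modules = pd.Series("m", index=z.columns)
        e1 = coexpr.module_eigengenes(z, modules)["m"]
        e2 = coexpr.module_eigengenes(-z, modules)["m"]
        assert abs(np.corrcoef(e1, e2)[0, 1]) == pytest.approx(1.0)

    def test_matches_svd_oracle(self, rng):
        z = pd.DataFrame(rng.normal(size=(3, 4)), columns=list("abcd"))
        z = (z - z.mean()) / z.std(ddof=1)
        eig = coexpr.module_eigengenes(z, pd.Series("m", index=z.columns))["m"]
        u, s, vt = np.linalg.svd(z.to_numpy(), full_matrices=False)
        assert abs(np.corrcoef(eig, u[:, 0])[0, 1]) == pytest.approx(1.0)
        assert np.linalg.norm(eig) == pytest.approx(1.0)


class TestModuleTrait:
    def test_self_trait_perfect_cor(self, rng):
        z = block_expression(rng, block_sizes=(10,), n_noise=0)
        modules = pd.Series("m", index=z.columns)
        eig = coexpr.module_eigengenes(z, modules)
        traits = pd.DataFrame({"t": eig["m"]})
        mt = coexpr.module_trait_correlations(eig, traits)
        assert mt["cor"].loc["m", "t"] == pytest.approx(1.0)
        assert mt["p"].loc["m", "t"] < 1e-10

    def test_closed_form_t_pvalue(self):
        """cor 0.81 over 11 samples gives t ~ 4.14, p ~ 2.5e-3."""
        r, n = 0.81, 11
        p = coexpr.corr_pvalues(np.array([r]), n)[0]
        t_expected = r * np.sqrt(n - 2) / np.sqrt(1 - r**2)
        assert t_expected == pytest.approx(4.14, abs=0.01)
        assert p == pytest.approx(2 * t_dist.sf(t_expected, n - 2))
        assert p == pytest.approx(2.5e-3, rel=0.05)

    def test_fdr_dominates_p(self, rng):
        z = block_expression(rng, block_sizes=(10, 10), n_noise=5)
        net = coexpr.build_network(z, min_module_size=8)
        traits = pd.DataFrame({"a": rng.normal(size=z.shape[0]),
                               "b": rng.normal(size=z.shape[0])})
        mt = coexpr.module_trait_correlations(net.eigengenes, traits)
        assert (mt["fdr"].to_numpy() >= mt["p"].to_numpy() - 1e-12).all()


class TestGeneStatistics:
    def make_stats(self, rng):
        z = block_expression(rng, block_sizes=(6,), n_noise=3, noise_sd=0.2)
        modules = pd.Series(coexpr.UNASSIGNED, index=z.columns)
        modules[[c for c in z.columns if c.startswith("b0")]] = "m"
        eig = coexpr.module_eigengenes(z, modules)
        adj = pd.DataFrame(
            coexpr.adjacency_signed(np.corrcoef(z.to_numpy().T), 6),
            index=z.columns, columns=z.columns)
        trait = pd.Series(rng.normal(size=z.shape[0]), index=z.index)
        return z, modules, eig, adj, trait

    def test_gene_equal_to_eigengene(self, rng):
        z, modules, eig, adj, trait = self.make_stats(rng)
        z2 = z.copy()
        z2["b0_0"] = eig["m"]
        stats = coexpr.gene_statistics(z2, eig, modules, trait, adj)
        assert stats.table.loc["b0_0", "MM"] == pytest.approx(1.0)

    def test_kim_matches_bruteforce(self, rng):
        z, modules, eig, adj, trait = self.make_stats(rng)
        stats = coexpr.gene_statistics(z, eig, modules, trait, adj)
        members = [c for c in z.columns if c.startswith("b0")]
        sums = {g: sum(adj.loc[g, h] for h in members if h != g)
                for g in members}
        mx = max(sums.values())
        for g in members:
            assert stats.table.loc[g, "kIM"] == pytest.approx(sums[g] / mx)

    def test_singleton_module_kim_zero(self, rng):
        z, _, _, adj, trait = self.make_stats(rng)
        modules = pd.Series(coexpr.UNASSIGNED, index=z.columns)
        modules["b0_0"] = "solo"
        eig = coexpr.module_eigengenes(z, modules)
        stats = coexpr.gene_statistics(z, eig, modules, trait, adj)
        assert stats.table.loc["b0_0", "kIM"] == 0.0


def test_export_edges_threshold(rng):
    genes = list("abcd")
    B = rng.uniform(0, 1, size=(4, 4))
    A = pd.DataFrame((B + B.T) / 2, index=genes, columns=genes)
    np.fill_diagonal(A.to_numpy(), 1.0)
    edges = coexpr.export_edges(A, threshold=0.5)
    expected = {(g1, g2) for i, g1 in enumerate(genes)
                for g2 in genes[i + 1:] if A.loc[g1, g2] > 0.5}
    assert set(zip(edges["gene1"], edges["gene2"])) == expected
    assert (edges["adjacency"] > 0.5).all()


class TestHubGenes:
    def test_zero_thresholds_whole_module(self, rng):
        z = block_expression(rng, block_sizes=(8,), n_noise=2, noise_sd=0.2)
        net = coexpr.build_network(z, min_module_size=5)
        trait = pd.Series(rng.normal(size=z.shape[0]), index=z.index)
        stats = coexpr.gene_statistics(z[net.modules.index], net.eigengenes,
                                       net.modules, trait, net.adjacency)
        mod = [m for m in net.modules.unique() if m != coexpr.UNASSIGNED][0]
        hubs = coexpr.hub_genes(stats, mod, mm_min=-1, kim_min=-1, adj_min=-1)
        assert set(hubs) == set(net.modules.index[net.modules == mod])

    def test_conjunction_semantics(self):
        table = pd.DataFrame(
            {"module": ["m", "m"], "MM": [0.9, 0.9], "MM_p": [0, 0],
             "GS": [0.9, 0.9], "GS_p": [0, 0], "kIM": [0.9, 0.9],
             "max_adj": [0.5, 0.2]},
            index=pd.Index(["good", "fails_adj"], name="gene"))
        stats = coexpr.GeneModuleStats(table=table)
        assert coexpr.hub_genes(stats, "m") == ["good"]
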