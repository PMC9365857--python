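import numpy as np
import pandas as pd
import pytest

from tuftnet import specificity as spec_mod
from tuftnet.coexpr import GeneModuleStats


def zdf(values, samples=None, genes=None):
    values = np.asarray(values, dtype=float)
    samples = samples or [f"S{i}" for i in range(values.shape[0])]
    genes = genes or [f"g{j}" for j in range(values.shape[1])]
    return pd.DataFrame(values, index=samples, columns=genes)


class TestEmpiricalP:
    def test_count_over_total_convention(self):
        assert spec_mod.empirical_p(550, 10000) == pytest.approx(0.055)

    def test_bounds(self):
        with pytest.raises(ValueError):
            spec_mod.empirical_p(-1, 100)
        with pytest.raises(ValueError):
            spec_mod.empirical_p(101, 100)


class TestGroupSamples:
    def test_three_vs_rest_split(self, rng):
        base = rng.normal(0, 0.1, size=(8, 6))
        base[:3] -= 2.0  # three clearly low samples
        part = spec_mod.group_samples_by_hub_genes(zdf(base), [f"g{j}" for j in range(6)])
        assert (part.iloc[:3] == "low").all()
        assert (part.iloc[3:] == "high").all()

    def test_degenerate_identical_samples(self):
        with pytest.raises(ValueError, match="degenerate"):
            spec_mod.group_samples_by_hub_genes(zdf(np.ones((5, 4))),
                                                ["g0", "g1"])

    def test_gene_label_swap_invariance(self, rng):
        x = rng.normal(size=(7, 5))
        part1 = spec_mod.group_samples_by_hub_genes(zdf(x), [f"g{j}" for j in range(5)])
        swapped = zdf(x[:, ::-1])
        part2 = spec_mod.group_samples_by_hub_genes(
            swapped, [f"g{j}" for j in range(5)])
        pd.testing.assert_series_equal(part1, part2)


class TestGroupingPermutation:
    def test_single_matching_perm(self, rng):
        """With n_genes = all genes every draw reproduces the observed split."""
        x = rng.normal(size=(6, 10))
        x[:3] += 4.0
        z = zdf(x)
        obs = spec_mod.group_samples_by_hub_genes(z, list(z.columns))
        sg = spec_mod.grouping_permutation_p(z, obs, n_genes=10, n_perm=1,
                                             seed=0)
        assert sg.empirical_p == 1.0
        assert sg.n_matches == 1

    def test_global_covariate_gives_high_p(self, rng):
        """A split present in every gene is reproduced by almost any draw."""
        offset = np.array([3.0] * 3 + [0.0] * 5)
        x = offset[:, None] + rng.normal(0, 0.2, size=(8, 40))
        z = zdf(x)
        obs = spec_mod.group_samples_by_hub_genes(z, list(z.columns)[:10])
        sg = spec_mod.grouping_permutation_p(z, obs, n_genes=10, n_perm=200,
                                             seed=1)
        assert sg.empirical_p > 0.9

    def test_bipartition_unordered(self):
        a = pd.Series(["high", "low", "high"], index=["s1", "s2", "s3"])
        b = pd.Series(["low", "high", "low"], index=["s1", "s2", "s3"])
        assert spec_mod._partition_key(a) == spec_mod._partition_key(b)

    def test_sample_relabelling_invariance(self, rng):
        x = rng.normal(size=(7, 30))
        x[:2] += 3
        z = zdf(x)
        obs = spec_mod.group_samples_by_hub_genes(z, list(z.columns)[:5])
        p1 = spec_mod.grouping_permutation_p(z, obs, n_perm=100, seed=5)
        z2 = z.copy()
        z2.index = [f"renamed{i}" for i in range(7)]
        obs2 = obs.copy()
        obs2.index = z2.index
        p2 = spec_mod.grouping_permutation_p(z2, obs2, n_perm=100, seed=5)
        assert p1.n_matches == p2.n_matches

    def test_too_many_genes_error(self, rng):
        z = zdf(rng.normal(size=(5, 4)))
        obs = pd.Series(["high", "low", "low", "high", "low"], index=z.index)
        with pytest.raises(ValueError):
            spec_mod.grouping_permutation_p(z, obs, n_genes=10)


def stats_table(rows):
    df = pd.DataFrame(rows).set_index("gene")
    return GeneModuleStats(table=df)


class TestAuxiliaryModule:
    def test_conjunction(self):
        stats = stats_table([
            {"gene": "a", "module": "m", "MM": 0.8, "MM_p": 0.0, "GS": 0.9,
             "GS_p": 0.001, "kIM": 0.5, "max_adj": 0.5},
            {"gene": "b", "module": "m", "MM": 0.3, "MM_p": 0.0, "GS": 0.6,
             "GS_p": 0.01, "kIM": 0.5, "max_adj": 0.5},  # fails MM
            {"gene": "c", "module": "other", "MM": 0.9, "MM_p": 0.0, "GS": 0.9,
             "GS_p": 0.001, "kIM": 0.5, "max_adj": 0.5},  # wrong module
        ])
        out = spec_mod.define_auxiliary_module(stats, ["a", "b", "c"], "m")
        assert out == ["a"]

    def test_permissive_thresholds_keep_all_module_targets(self):
        stats = stats_table([
            {"gene": g, "module": "m", "MM": 0.4, "MM_p": 0.0, "GS": 0.1,
             "GS_p": 0.5, "kIM": 0.0, "max_adj": 0.0}
            for g in ["a", "b"]
        ])
        out = spec_mod.define_auxiliary_module(stats, ["a", "b"], "m",
                                               gs_min=-1, gs_p_max=1.1,
                                               mm_min=-1)
        assert out == ["a", "b"]


class TestPreservation:
    def make_percluster(self, rng, n_samples=10, n_aux=8):
        genes = [f"aux{j}" for j in range(n_aux)] + ["other1", "other2"]
        latent = rng.normal(size=n_samples)
        ref = np.column_stack(
            [latent + rng.normal(0, 0.3, n_samples) for _ in range(n_aux)]
            + [rng.normal(size=n_samples) for _ in range(2)])
        ref = (ref - ref.mean(0)) / ref.std(0, ddof=1)
        return {"ref": zdf(ref, genes=genes)}, [f"aux{j}" for j in range(n_aux)]

    def test_reference_is_one(self, rng):
        pcz, aux = self.make_percluster(rng)
        pcz["copy"] = pcz["ref"].copy()
        res = spec_mod.preservation_cor_kme(pcz, "ref", aux)
        assert res.table.loc["ref", "cor_kme"] == 1.0
        assert res.table.loc["copy", "cor_kme"] == pytest.approx(1.0)

    def test_permuted_cluster_centred_on_zero(self, rng):
        cors = []
        for _ in range(40):
            pcz, aux = self.make_percluster(rng)
            perm = pcz["ref"].copy()
            for c in perm.columns:  # destroy gene-gene structure
                perm[c] = rng.permutation(perm[c].to_numpy())
            pcz["null"] = perm
            res = spec_mod.preservation_cor_kme(pcz, "ref", aux)
            cors.append(res.table.loc["null", "cor_kme"])
        m = np.mean(cors)
        se = np.std(cors, ddof=1) / np.sqrt(len(cors))
        assert abs(m) < 4 * se + 0.1

    def test_cluster_with_single_gene_excluded(self, rng):
        pcz, aux = self.make_percluster(rng)
        degen = pcz["ref"].copy()
        for g in aux[1:]:
            degen[g] = 1.0  # zero variance: unusable
        pcz["degen"] = degen
        res = spec_mod.preservation_cor_kme(pcz, "ref", aux)
        assert "degen" not in res.table.index


class TestCorrelationPanel:
    def test_identical_pair_unmasked(self, rng):
        x = rng.normal(size=(10, 3))
        x[:, 1] = x[:, 0]
        out = spec_mod.pairwise_correlation_panel({"c": zdf(x)},
                                                  ["g0", "g1", "g2"])
        assert out["c"]["cor"].loc["g0", "g1"] == pytest.approx(1.0)
        assert bool(out["c"]["mask"].loc["g0", "g1"])

    def test_low_power_masks_most(self, rng):
        x = rng.normal(size=(3, 6))
        out = spec_mod.pairwise_correlation_panel({"c": zdf(x)},
                                                  [f"g{j}" for j in range(6)])
        frac_sig = out["c"]["mask"].to_numpy().mean()
        assert frac_sig < 0.5


class TestVarianceFoldChange:
    def test_identical_inputs_unit_fc(self, rng):
        v = pd.Series(rng.uniform(0.5, 2, 50), index=[f"g{j}" for j in range(50)])
        res = spec_mod.variance_foldchange_test(v, v.copy(),
                                                [f"g{j}" for j in range(5)],
                                                n_perm=500, n_boot=200, seed=0)
        assert res["mean"] == pytest.approx(1.0)
        assert res["median"] == pytest.approx(1.0)
        assert res["p"] > 0.1

    def test_planted_inflation_floor_p(self, rng):
        genes = [f"g{j}" for j in range(200)]
        vb = pd.Series(rng.uniform(0.5, 2, 200), index=genes)
        va = vb.copy()
        targets = genes[:10]
        va[targets] *= 3.0
        res = spec_mod.variance_foldchange_test(va, vb, targets, n_perm=1000,
                                                n_boot=200, seed=0)
        assert res["p"] == pytest.approx(1 / 1001)

    def test_single_target(self, rng):
        genes = ["a", "b", "c"]
        va = pd.Series([2.0, 1.0, 1.0], index=genes)
        vb = pd.Series([1.0, 1.0, 1.0], index=genes)
        res = spec_mod.variance_foldchange_test(va, vb, ["a"], n_perm=100,
                                                n_boot=50, seed=0)
        assert res["mean"] == res["median"] == pytest.approx(2.0)

    def test_zero_variance_target_dropped(self, rng):
        genes = ["a", "b", "c", "d"]
        va = pd.Series([2.0, 0.0, 1.0, 1.5], index=genes)
        vb = pd.Series([1.0, 1.0, 1.0, 1.0], index=genes)
        with pytest.warns(UserWarning, match="dropped"):
            res = spec_mod.variance_foldchange_test(va, vb, ["a", "b"],
                                                    n_perm=100, n_boot=50,
                                                    seed=0)
        assert list(res["fold_changes"].index) == ["a"]


def test_percluster_variability_argmax(small_cohort):
    """Planted module genes are most variable in the rare cluster.

    Raw single-cell variance is the within-cohort measure of record: the
    near-silent pseudo-bulk of these genes in other clusters is dominated
    by log-CPM shot noise at this cohort size.
    """
    cfg, adata, truth = small_cohort
    table = spec_mod.percluster_variability(
        adata, truth.cell_cluster, genes=truth.module_members[:10])
    arg = spec_mod.variability_argmax(table, "sc_raw_var")
    assert (arg == cfg.rare_cluster_index).mean() >= 0.8
    assert set(table.columns) == {"pb_z_var", "sc_raw_var", "sc_std_var"}
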