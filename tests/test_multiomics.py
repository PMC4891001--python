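import numpy as np
import pandas as pd
import pytest
import scipy.stats as st

from conftest import random_monotone_map
from oracles import fisher_two_sided_enum, pearson_on_midranks, \
    rank_product_null_bruteforce
from reosig._stats import fisher_two_sided
from reosig.concordance import concordance_binomial
from reosig.io import DiscreteOmicsMatrix, ExpressionMatrix, PPINetwork
from reosig.multiomics import (aggregate_regions, cn_expression_correlation,
                               direction_imbalance, group_frequency_test,
                               median_center_batches,
                               methylation_expression_integration,
                               ppi_link_enrichment, rank_products)
from reosig.simulate import SimulationConfig, gen_multiomics


def _df(values, genes=None, samples=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{i}" for i in range(values.shape[1])]
    return pd.DataFrame(values, index=genes, columns=samples)


def _labels(n_high, n_low):
    idx = [f"T{i}" for i in range(n_high + n_low)]
    return pd.Series(["high"] * n_high + ["low"] * n_low, index=idx)


class TestRankProducts:
    def test_uniformly_top_ranked_gene_attains_rp_one(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(0, 1, size=(8, 6))
        vals[0, :3] += 50.0          # top within-sample rank in every A sample
        vals[0, 3:] -= 50.0          # bottom rank in every B sample
        df = _df(vals)
        res = rank_products(df, ["s0", "s1", "s2"], ["s3", "s4", "s5"],
                            n_perm=10, seed=1)
        assert res.table.loc["g0", "rp_up"] == pytest.approx(1.0)
        assert res.table.loc["g0", "rank_up"] == 1

    def test_exact_pfp_matches_bruteforce_enumeration(self):
        """5 genes, 3 vs 3 samples (9 pairings): the exact-null pFP equals
        enumeration over all 5**9 rank combinations."""
        rng = np.random.default_rng(2)
        df = _df(rng.normal(0, 1, size=(5, 6)))
        a, b = ["s0", "s1", "s2"], ["s3", "s4", "s5"]
        res = rank_products(df, a, b, exact_null=True, seed=0)
        k = res.n_pairings
        assert k == 9
        for direction in ("up", "down"):
            rp = res.table[f"rp_{direction}"].to_numpy()
            expected_counts = rank_product_null_bruteforce(5, k, rp ** k)
            order = np.argsort(rp, kind="stable")
            ranks = np.empty(5)
            ranks[order] = np.arange(1, 6)
            pfp = expected_counts / ranks
            pfp_monotone = np.empty(5)
            pfp_monotone[order] = np.maximum.accumulate(pfp[order])
            assert np.allclose(res.table[f"pfp_{direction}"], pfp_monotone,
                               rtol=1e-9)

    def test_permutation_pfp_converges_to_exact_null(self):
        rng = np.random.default_rng(3)
        df = _df(rng.normal(0, 1, size=(5, 6)))
        a, b = ["s0", "s1", "s2"], ["s3", "s4", "s5"]
        exact = rank_products(df, a, b, exact_null=True, seed=0)
        mc = rank_products(df, a, b, n_perm=4000, seed=0)
        assert np.allclose(mc.table["pfp_up"], exact.table["pfp_up"], atol=0.15)

    def test_invariant_under_monotone_per_sample_transforms(self):
        """A different strictly monotone map per sample leaves the whole
        result table bit-identical (within-sample ranks are unchanged)."""
        rng = np.random.default_rng(4)
        df = _df(rng.normal(5, 2, size=(30, 10)))
        a = [f"s{i}" for i in range(5)]
        b = [f"s{i}" for i in range(5, 10)]
        base = rank_products(df, a, b, n_perm=20, seed=5)
        for _ in range(5):
            transformed = df.copy()
            for c in df.columns:
                transformed[c] = random_monotone_map(rng)(df[c].to_numpy())
            res = rank_products(transformed, a, b, n_perm=20, seed=5)
            pd.testing.assert_frame_equal(res.table, base.table)

    def test_recovers_planted_hypermethylation(self):
        labels = _labels(60, 25)
        _, _, meth, _, truth = gen_multiomics(SimulationConfig(seed=21), labels)
        res = rank_products(meth, truth["high"], truth["low"], n_perm=60,
                            fdr=0.20, seed=6)
        hyper = set(res.significant("up"))
        planted = set(truth["hypermethylated_genes"])
        assert len(hyper & planted) / len(planted) >= 0.8

    def test_group_too_small_rejected(self):
        df = _df(np.zeros((3, 3)))
        with pytest.raises(ValueError, match="2 samples"):
            rank_products(df, ["s0"], ["s1", "s2"])


class TestGroupFrequencyTest:
    def _cn(self, rows, samples=None):
        df = _df(rows, samples=samples)
        return DiscreteOmicsMatrix(df.astype(int), mode="cn")

    def test_identical_frequencies_give_p_one(self):
        m = self._cn([[1, 1, 0, 0, 1, 1, 0, 0]])
        res = group_frequency_test(m, [f"s{i}" for i in range(4)],
                                   [f"s{i}" for i in range(4, 8)], event="gain")
        assert res["fisher_p"].iloc[0] == pytest.approx(1.0)

    def test_extreme_table_matches_hypergeometric_value(self):
        # 10/10 gained vs 0/10: two-sided p = 2 / C(20,10)
        m = self._cn([[1] * 10 + [0] * 10])
        res = group_frequency_test(m, [f"s{i}" for i in range(10)],
                                   [f"s{i}" for i in range(10, 20)],
                                   event="gain")
        assert res["fisher_p"].iloc[0] == pytest.approx(1.0824e-05, rel=1e-3)

    def test_planted_region_flagged_at_fdr(self):
        labels = _labels(100, 40)
        cn, _, _, _, truth = gen_multiomics(SimulationConfig(seed=22), labels)
        regions = aggregate_regions(cn, truth["gene_to_region"])
        res = group_frequency_test(regions, truth["high"], truth["low"],
                                   event="gain", correction="bh_fdr",
                                   threshold=0.20)
        planted = set(truth["planted_gain_regions"])
        flagged = set(res.index[res["significant"]])
        assert planted <= flagged

    def test_event_mode_compatibility_enforced(self):
        m = self._cn([[0, 1]])
        with pytest.raises(ValueError, match="mutation-mode"):
            group_frequency_test(m, ["s0"], ["s1"], event="mutated")


class TestDirectionImbalance:
    def _results(self, k, s):
        return pd.DataFrame({
            "significant": [True] * k,
            "direction": ["b"] * s + ["a"] * (k - s),
        })

    def test_155_of_156_below_machine_bound(self):
        res = direction_imbalance(self._results(156, 155))
        assert res.p_value <= 1.11e-16

    def test_balanced_directions(self):
        res = direction_imbalance(self._results(10, 5))
        assert res.p_value == pytest.approx(0.6230, abs=1e-4)

    def test_unanimous_three(self):
        res = direction_imbalance(self._results(3, 3))
        assert res.p_value == pytest.approx(0.125, rel=1e-12)

    def test_no_significant_features_errors(self):
        df = pd.DataFrame({"significant": [False], "direction": ["a"]})
        with pytest.raises(ValueError, match="k = 0"):
            direction_imbalance(df)


class TestCnExpressionCorrelation:
    def test_monotone_dosage_response_has_rho_one(self):
        cn = DiscreteOmicsMatrix(_df([[0, 1, 2, 1, 0]]).astype(int), mode="cn")
        expr = ExpressionMatrix(_df([[1.0, 2.0, 3.0, 2.0, 1.0]]))
        out = cn_expression_correlation(cn, expr, {"g0": "7p22.1"},
                                        ["s0", "s1", "s2"], ["s3", "s4"])
        assert out.loc["g0", "spearman_rho"] == pytest.approx(1.0)

    def test_constant_cn_excluded(self):
        cn = DiscreteOmicsMatrix(_df([[1, 1, 1, 1, 1]]).astype(int), mode="cn")
        expr = ExpressionMatrix(_df([[1.0, 2.0, 3.0, 4.0, 5.0]]))
        out = cn_expression_correlation(cn, expr, {"g0": "7p22.1"},
                                        ["s0", "s1"], ["s2", "s3", "s4"])
        assert bool(out.loc["g0", "excluded"])

    def test_rho_equals_pearson_on_midranks_oracle(self):
        cn_states = [0, 1, 2, 2, 0]
        exprs = [1.0, 2.0, 3.5, 3.0, 0.5]
        cn = DiscreteOmicsMatrix(_df([cn_states]).astype(int), mode="cn")
        expr = ExpressionMatrix(_df([exprs]))
        out = cn_expression_correlation(cn, expr, {"g0": "7p22.1"},
                                        ["s0", "s1", "s2"], ["s3", "s4"])
        oracle = pearson_on_midranks(cn_states, exprs)
        assert out.loc["g0", "spearman_rho"] == pytest.approx(oracle, abs=1e-12)

    def test_spearman_without_ties_equals_pearson_on_ranks(self):
        rng = np.random.default_rng(1)
        x = rng.permutation(10).astype(float)
        y = rng.normal(size=10)
        rho = st.spearmanr(x, y).statistic
        assert rho == pytest.approx(pearson_on_midranks(x, y), abs=1e-12)


class TestPPILinkEnrichment:
    def _net_from_table(self, table, rng_seed=0):
        """Build a network realizing exact linked counts for the 2x2 table."""
        (lq, uq), (lb, ub) = table
        edges = []
        query = [f"q{i}" for i in range(lq + uq)]
        background = [f"b{i}" for i in range(lb + ub)]
        for g in query[:lq] + background[:lb]:
            edges.append((g, "REF1"))
        net = PPINetwork.from_edges(edges)
        net.graph.add_nodes_from(query + background + ["REF1"])
        return net, query, background

    @pytest.mark.parametrize("table,expected", [
        (((11, 74), (21, 497)), 2.41e-03),
        (((19, 308), (191, 12285)), 1.83e-06),
    ])
    def test_printed_fisher_values_reproduced(self, table, expected):
        net, query, background = self._net_from_table(table)
        res = ppi_link_enrichment(net, query, ["REF1"], background)
        assert res.table == table
        assert res.fisher_p == pytest.approx(expected, rel=5e-3)

    def test_balanced_fractions_give_p_one(self):
        net, query, background = self._net_from_table(((5, 5), (50, 50)))
        res = ppi_link_enrichment(net, query, ["REF1"], background)
        assert res.fisher_p == pytest.approx(1.0)

    def test_overlapping_query_background_rejected(self):
        net = PPINetwork.from_edges([("a", "b")])
        with pytest.raises(ValueError, match="disjoint"):
            ppi_link_enrichment(net, ["a"], ["b"], ["a", "c"])


class TestMethylationExpressionIntegration:
    def _rp_result(self, genes, direction_up, sig=True):
        from reosig.multiomics import RankProductsResult
        n = len(genes)
        up = np.asarray(direction_up, dtype=bool)
        table = pd.DataFrame({
            "rp_up": np.arange(1, n + 1, dtype=float),
            "rp_down": np.arange(n, 0, -1, dtype=float),
            "rank_up": np.arange(1, n + 1),
            "rank_down": np.arange(n, 0, -1),
            "pfp_up": np.where(up, 0.01, 0.9),
            "pfp_down": np.where(up, 0.9, 0.01),
            "mean_diff": np.where(up, 1.0, -1.0),
            "direction": np.where(up, 1, -1),
            "sig_up": up & sig, "sig_down": ~up & sig,
        }, index=genes)
        return RankProductsResult(table=table, n_pairings=9, n_perm=100, fdr=0.2)

    def test_known_counts_reproduce_printed_score(self):
        n_hyper, k, s = 500, 400, 327
        genes = [f"g{i}" for i in range(600)]
        hyper = genes[:n_hyper]
        dmg = self._rp_result(genes, [i < n_hyper for i in range(600)])
        # DEGs: the first k hypermethylated genes (s of them down-regulated)
        # plus a few hypomethylated up-regulated genes
        deg_genes = hyper[:k] + genes[n_hyper:n_hyper + 10]
        deg_dirs = [-1] * s + [1] * (k - s) + [1] * 10
        deg = pd.DataFrame({"significant": [True] * (k + 10),
                            "direction": deg_dirs}, index=deg_genes)
        out = methylation_expression_integration(dmg, deg)
        res = out["hyper_down"]["result"]
        assert (res.k, res.s) == (400, 327)
        assert res.score == pytest.approx(0.8175)
        assert res.p_value <= 1.11e-16

    def test_fully_concordant_directions_score_one(self):
        genes = [f"g{i}" for i in range(10)]
        dmg = self._rp_result(genes, [True] * 5 + [False] * 5)
        deg = pd.DataFrame({"significant": [True] * 10,
                            "direction": [-1] * 5 + [1] * 5}, index=genes)
        out = methylation_expression_integration(dmg, deg)
        assert out["hyper_down"]["result"].score == 1.0
        assert out["hypo_up"]["result"].score == 1.0


class TestFisherAgainstEnumeration:
    def test_small_tables_match_exact_enumeration(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            a, b, c, d = rng.integers(0, 13, size=4)
            if (a + b == 0) or (c + d == 0):
                continue
            table = [[int(a), int(b)], [int(c), int(d)]]
            _, p = fisher_two_sided(table)
            assert p == pytest.approx(fisher_two_sided_enum(table), rel=1e-8)


def test_region_aggregation_takes_max_state():
    cn = DiscreteOmicsMatrix(_df([[0, 2], [1, 0], [0, -1]]).astype(int),
                             mode="cn")
    regions = aggregate_regions(cn, {"g0": "R1", "g1": "R1", "g2": "R2"})
    assert regions.states.loc["R1"].tolist() == [1, 2]
    assert regions.states.loc["R2"].tolist() == [0, -1]


def test_median_centering_zeroes_per_batch_medians():
    rng = np.random.default_rng(5)
    df = _df(rng.normal(5, 1, size=(10, 6)))
    expr = ExpressionMatrix(df)
    batch = pd.Series(["b1"] * 3 + ["b2"] * 3, index=df.columns)
    out = median_center_batches(expr, batch)
    for b_cols in (df.columns[:3], df.columns[3:]):
        med = out.values[b_cols].median(axis=1)
        assert np.allclose(med, 0.0, atol=1e-12)
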