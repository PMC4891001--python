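import dataclasses

import numpy as np
import pandas as pd
import pytest
import scipy.stats as st
from hypothesis import given, settings, strategies as stnum

from conftest import random_monotone_map
from oracles import bh_bruteforce, cox_univariate_newton
from reosig._stats import bh_qvalues
from reosig.classify import REOSignature
from reosig.discovery import (assemble_signature, deg_ttest,
                              gi50_correlation_filter, os_association_filter,
                              reo_pair_scan)
from reosig.io import DrugResponseTable, ExpressionMatrix, SurvivalTable
from reosig.simulate import (CellLineArm, PatientArm, SimulationConfig,
                             gen_cell_line_cohort, gen_patient_cohort)


def _expr(values, genes=None, samples=None, **kw):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{i}" for i in range(values.shape[1])]
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples), **kw)


class TestDegTtest:
    def test_identical_group_values_yield_no_degs(self):
        rng = np.random.default_rng(0)
        block = rng.normal(size=(40, 5))
        m = _expr(np.hstack([block, block]))
        out = deg_ttest(m, [f"s{i}" for i in range(5)],
                        [f"s{i}" for i in range(5, 10)], fdr=0.99)
        assert out["significant"].sum() == 0
        assert (out["p_value"] == 1.0).all() | (out["degenerate"]).all() \
            or out["p_value"].min() >= 0.99  # identical values: t = 0, p = 1

    def test_pooled_variance_closed_form(self):
        m = _expr([[1.0, 2.0, 3.0, 4.0, 5.0, 6.0]])
        out = deg_ttest(m, ["s0", "s1", "s2"], ["s3", "s4", "s5"],
                        equal_var=True)
        assert out.loc["g0", "statistic"] == pytest.approx(-3.674, abs=1e-3)
        assert out.loc["g0", "p_value"] == pytest.approx(0.0213, abs=2e-4)
        assert out.loc["g0", "direction"] == -1

    def test_zero_variance_both_groups_flagged(self):
        m = _expr([[5.0] * 6, [1, 2, 3, 7, 8, 9]])
        out = deg_ttest(m, ["s0", "s1", "s2"], ["s3", "s4", "s5"])
        assert bool(out.loc["g0", "degenerate"])
        assert out.loc["g0", "p_value"] == 1.0
        assert not out.loc["g1", "degenerate"]

    def test_overlapping_groups_rejected(self, tiny_expr):
        with pytest.raises(ValueError, match="disjoint"):
            deg_ttest(tiny_expr, ["S1", "S2"], ["S2", "S3"])

    def test_recovers_planted_degs_on_balanced_panel(self):
        """14 vs 14 lines, 100 planted 1.5-sigma DEGs among 2000 genes:
        recall at FDR < 0.20 should reach 0.8."""
        cfg = SimulationConfig(seed=5, cell=CellLineArm(
            n_resistant=14, n_sensitive=14, n_gi50_genes=0))
        expr, _, truth = gen_cell_line_cohort(cfg)
        out = deg_ttest(expr, truth["resistant"], truth["sensitive"], fdr=0.20)
        hits = set(out.index[out["significant"]])
        recall = len(hits & set(truth["planted_degs"])) / len(truth["planted_degs"])
        assert recall >= 0.8


class TestGi50CorrelationFilter:
    def _response(self, values, cells):
        return DrugResponseTable(pd.Series(values, index=cells, name="gi50"))

    def test_gene_proportional_to_gi50_has_r_one(self):
        m = _expr([[1.0, 2.0, 3.0]])
        resp = self._response([2.0, 4.0, 6.0], ["s0", "s1", "s2"])
        out = gi50_correlation_filter(m, resp, ["g0"])
        assert out.loc["g0", "statistic"] == pytest.approx(1.0)
        assert out.loc["g0", "p_value"] <= 1e-6

    def test_constant_gene_flagged_not_significant(self):
        m = _expr([[1.0, 1.0, 1.0, 1.0], [1, 2, 3, 4]])
        resp = self._response([1.0, 2.0, 3.0, 4.0], [f"s{i}" for i in range(4)])
        out = gi50_correlation_filter(m, resp, ["g0", "g1"], fdr=0.5)
        assert bool(out.loc["g0", "degenerate"])
        assert not out.loc["g0", "significant"]
        assert out.loc["g1", "significant"]

    def test_null_genes_yield_no_survivors_over_seeds(self):
        """Independent genes vs random GI50: FDR control leaves ~0 survivors."""
        total = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            m = _expr(rng.normal(size=(100, 28)))
            resp = self._response(rng.lognormal(0, 1, 28),
                                  [f"s{i}" for i in range(28)])
            out = gi50_correlation_filter(m, resp, list(m.gene_ids), fdr=0.20)
            total += int(out["significant"].sum())
        assert total <= 2


class TestOsAssociationFilter:
    def test_constant_gene_excluded(self):
        rng = np.random.default_rng(0)
        n = 30
        m = _expr(np.vstack([np.full(n, 3.0), rng.normal(size=n)]),
                  samples=[f"p{i}" for i in range(n)])
        surv = SurvivalTable(pd.DataFrame(
            {"time": rng.exponential(10, n), "event": [1] * n},
            index=[f"p{i}" for i in range(n)]))
        out = os_association_filter(m, surv, ["g0", "g1"])
        assert bool(out.loc["g0", "degenerate"])

    def test_null_kept_rate_near_alpha(self):
        kept = trials = 0
        for seed in range(25):
            rng = np.random.default_rng(seed)
            n, g = 50, 8
            m = _expr(rng.normal(size=(g, n)), samples=[f"p{i}" for i in range(n)])
            surv = SurvivalTable(pd.DataFrame(
                {"time": rng.exponential(10, n),
                 "event": (rng.random(n) < 0.8).astype(int)},
                index=[f"p{i}" for i in range(n)]))
            out = os_association_filter(m, surv, list(m.gene_ids), alpha=0.05)
            kept += int(out["significant"].sum())
            trials += g
        assert 0.01 <= kept / trials <= 0.10

    def test_planted_beta_recovered_and_matches_newton_oracle(self):
        rng = np.random.default_rng(2)
        n, beta = 300, 1.0
        x = rng.normal(0, 1, n)
        t = rng.exponential(1.0 / (0.05 * np.exp(beta * x)))
        samples = [f"p{i}" for i in range(n)]
        m = _expr(x[None, :], genes=["gx"], samples=samples)
        surv = SurvivalTable(pd.DataFrame({"time": t, "event": [1] * n},
                                          index=samples))
        out = os_association_filter(m, surv, ["gx"])
        assert 0.7 <= out.loc["gx", "statistic"] <= 1.3
        beta_oracle, _ = cox_univariate_newton(t, np.ones(n, dtype=int), x)
        assert out.loc["gx", "statistic"] == pytest.approx(beta_oracle, abs=1e-4)


class TestReoPairScan:
    def test_constant_reo_recorded_as_skipped(self):
        rng = np.random.default_rng(0)
        n = 20
        samples = [f"p{i}" for i in range(n)]
        vals = np.vstack([np.full(n, 1.0), np.full(n, 2.0),
                          rng.normal(5, 1, n)])
        m = _expr(vals, genes=["lo", "hi", "mid"], samples=samples)
        surv = SurvivalTable(pd.DataFrame(
            {"time": rng.exponential(10, n), "event": [1] * n}, index=samples))
        res = reo_pair_scan(m, surv, ["lo", "hi", "mid"])
        skipped_pairs = {(a, b) for a, b, _ in res.skipped}
        assert ("lo", "hi") in skipped_pairs

    def test_planted_pair_detected_with_planted_direction(self):
        cfg = SimulationConfig(seed=1, patient=PatientArm(
            n_patients=200, hazard_ratio=3.0))
        expr, surv, truth = gen_patient_cohort(cfg)
        res = reo_pair_scan(expr, surv, ["KCNE2", "PRPF3", "API5"], alpha=0.05)
        found = {(p.gene_a, p.gene_b): p.high_risk_order for p in res.pairs}
        for a, b, order in truth["planted_pairs"]:
            assert found.get((a, b)) == order

    def test_null_retained_rate_near_alpha(self):
        retained = tested = 0
        for seed in range(30):
            cfg = SimulationConfig(seed=seed, patient=PatientArm(
                n_patients=60, hazard_ratio=1.0))
            expr, surv, _ = gen_patient_cohort(cfg)
            res = reo_pair_scan(expr, surv, ["KCNE2", "PRPF3", "API5"],
                                alpha=0.05)
            retained += len(res.pairs)
            tested += res.tested
        assert tested > 0
        assert retained / tested <= 0.12

    def test_too_few_candidates_rejected(self, tiny_expr):
        surv = SurvivalTable(pd.DataFrame({"time": [1.0], "event": [1]},
                                          index=["S1"]))
        with pytest.raises(ValueError, match="2 candidate"):
            reo_pair_scan(tiny_expr, surv, ["GA"])


class TestAssembleSignature:
    def test_two_pair_unanimous_rule(self):
        sig = assemble_signature([("KCNE2", "PRPF3", "a<b"),
                                  ("KCNE2", "API5", "a<b")])
        assert isinstance(sig, REOSignature)
        assert len(sig.pairs) == 2
        assert sig.genes == ["KCNE2", "PRPF3", "API5"]

    def test_single_pair_signature(self):
        sig = assemble_signature([("A", "B", "a>b")])
        assert len(sig.pairs) == 1

    def test_empty_list_errors(self):
        with pytest.raises(ValueError, match="zero pairs"):
            assemble_signature([])


class TestMonotoneTransformBehaviour:
    def test_reo_stage_invariant_ttest_stage_not(self):
        """A per-sample strictly monotone transform leaves every within-sample
        ordering unchanged but alters t statistics."""
        rng = np.random.default_rng(9)
        m = _expr(rng.normal(5, 2, size=(10, 8)))
        maps = [random_monotone_map(rng) for _ in range(m.shape[1])]
        transformed = m.values.copy()
        for j, f in enumerate(maps):
            transformed.iloc[:, j] = f(transformed.iloc[:, j].to_numpy())
        mt = ExpressionMatrix(transformed)
        # orderings preserved
        for s in m.sample_ids:
            assert (np.argsort(m.values[s].to_numpy(), kind="stable")
                    == np.argsort(mt.values[s].to_numpy(), kind="stable")).all()
        # t statistics change
        a, b = m.sample_ids[:4], m.sample_ids[4:]
        t0 = deg_ttest(m, a, b)["statistic"]
        t1 = deg_ttest(mt, a, b)["statistic"]
        assert not np.allclose(t0, t1)


@settings(max_examples=60, derandomize=True)
@given(stnum.lists(stnum.floats(min_value=0.0, max_value=1.0), min_size=1,
                   max_size=40))
def test_bh_qvalues_match_bruteforce(ps):
    got = bh_qvalues(ps)
    expected = bh_bruteforce(ps)
    assert np.allclose(got, expected, atol=1e-12)


def test_null_funnel_yields_no_signature_pairs_in_most_seeds():
    """With zero planted effects the full funnel should end empty nearly
    always at the standard thresholds."""
    n_with_pairs = 0
    for seed in range(12):
        cfg = SimulationConfig(seed=seed, cell=CellLineArm(
            n_genes=300, deg_effect=0.0, gi50_correlation=0.0,
            gi50_group_separation=0.0),
            patient=PatientArm(hazard_ratio=1.0, n_patients=40))
        expr, gi50, truth = gen_cell_line_cohort(cfg)
        degs = deg_ttest(expr, truth["resistant"], truth["sensitive"], fdr=0.20)
        cands = list(degs.index[degs["significant"]])
        if not cands:
            continue
        corr = gi50_correlation_filter(expr, gi50, cands, fdr=0.20)
        gi50_hits = list(corr.index[corr["significant"]])
        if len(gi50_hits) < 2:
            continue
        pexpr, psurv, _ = gen_patient_cohort(cfg)
        shared = [g for g in gi50_hits if g in set(pexpr.gene_ids)]
        if len(shared) < 2:
            continue
        res = reo_pair_scan(pexpr, psurv, shared, alpha=0.05)
        n_with_pairs += bool(res.pairs)
    assert n_with_pairs <= 1
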