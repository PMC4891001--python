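"""The candidate-gene funnel and REO pair scan that build a prognostic signature.

Discovery proceeds in four stages, each narrowing the candidate list:

1. ``deg_ttest`` — genes differentially expressed between drug-resistant and
   drug-sensitive cell lines (t-test, BH FDR);
2. ``gi50_correlation_filter`` — of those, genes whose expression correlates
   with GI50 drug response (Pearson, BH within the candidate set only; the
   pre-selection is what makes the FDR control attainable at panel sizes of
   a few dozen cell lines);
3. ``os_association_filter`` — of those, genes associated with overall
   survival in a treated patient cohort (univariate Cox on continuous
   expression);
4. ``reo_pair_scan`` — every unordered pair of surviving genes is turned
   into a within-sample ordering split and tested for survival difference;
   significant pairs are assembled into an REO signature with the unanimous
   high-risk vote rule.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as st

from ._stats import bh_qvalues
from .classify import REOSignature, SignaturePair
from .io import ExpressionMatrix, DrugResponseTable, SurvivalTable
from .survival import cox_fit, km_logrank, _CoxFailure

__all__ = ["PrognosticPair", "deg_ttest", "gi50_correlation_filter",
           "os_association_filter", "reo_pair_scan", "assemble_signature"]


def _stat_table(genes, statistic, p, direction=None, degenerate=None,
                fdr=None, alpha=None) -> pd.DataFrame:
    """Assemble a per-gene statistic table with BH q-values and flags."""
    out = pd.DataFrame(index=pd.Index(genes, name="gene_id"))
    out["statistic"] = np.asarray(statistic, dtype=float)
    out["p_value"] = np.asarray(p, dtype=float)
    out["q_value"] = bh_qvalues(out["p_value"])
    out["direction"] = np.sign(out["statistic"]) if direction is None else direction
    out["degenerate"] = False if degenerate is None else np.asarray(degenerate)
    if fdr is not None:
        out["significant"] = (out["q_value"] < fdr) & ~out["degenerate"]
    elif alpha is not None:
        out["significant"] = (out["p_value"] < alpha) & ~out["degenerate"]
    return out


def deg_ttest(expr: ExpressionMatrix, group_a_ids, group_b_ids,
              fdr: float = 0.20, equal_var: bool = False) -> pd.DataFrame:
    """Two-sided t-test per gene between two sample groups, BH-adjusted.

    Welch's unequal-variance form is the default; pass ``equal_var=True``
    for the pooled-variance Student form. ``direction`` is +1 when the gene
    is up in group A. Genes with zero variance in both groups are flagged
    degenerate with p = 1.
    """
    group_a_ids, group_b_ids = list(group_a_ids), list(group_b_ids)
    if set(group_a_ids) & set(group_b_ids):
        raise ValueError("groups must be disjoint")
    if min(len(group_a_ids), len(group_b_ids)) < 2:
        raise ValueError("each group needs at least 2 samples")
    a = expr.values[group_a_ids].to_numpy(dtype=float)
    b = expr.values[group_b_ids].to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = st.ttest_ind(a, b, axis=1, equal_var=equal_var)
    degenerate = (a.var(axis=1) == 0) & (b.var(axis=1) == 0)
    t = np.where(degenerate, 0.0, t)
    p = np.where(degenerate, 1.0, p)
    return _stat_table(expr.gene_ids, t, p, degenerate=degenerate, fdr=fdr)


def gi50_correlation_filter(expr: ExpressionMatrix, gi50: DrugResponseTable,
                            candidates, fdr: float = 0.20) -> pd.DataFrame:
    """Pearson correlation of candidate genes against GI50 drug response.

    BH adjustment runs within the candidate set only. GI50 values are used
    on their stored scale. Constant genes (or constant GI50) have no defined
    correlation and are flagged degenerate with p = 1.
    """
    candidates = list(candidates)
    missing = set(candidates) - set(expr.gene_ids)
    if missing:
        raise KeyError(f"candidate gene(s) absent from matrix: {sorted(missing)[:5]}")
    cells = [c for c in expr.sample_ids if c in gi50.gi50.index]
    if len(cells) < 3:
        raise ValueError("need at least 3 cell lines shared with the GI50 table")
    y = gi50.gi50.reindex(cells).to_numpy(dtype=float)
    y_const = np.ptp(y) == 0
    rows_r, rows_p, degen = [], [], []
    X = expr.values.loc[candidates, cells].to_numpy(dtype=float)
    for x in X:
        if y_const or np.ptp(x) == 0:
            rows_r.append(0.0)
            rows_p.append(1.0)
            degen.append(True)
            continue
        r, p = st.pearsonr(x, y)
        rows_r.append(r)
        rows_p.append(max(p, np.finfo(float).tiny))
        degen.append(False)
    return _stat_table(candidates, rows_r, rows_p, degenerate=degen, fdr=fdr)


def os_association_filter(expr: ExpressionMatrix, survival: SurvivalTable,
                          candidates, alpha: float = 0.05,
                          ties: str = "efron") -> pd.DataFrame:
    """Univariate Cox of overall survival on each candidate's continuous expression.

    ``statistic`` is the log-hazard beta. Genes whose fit does not converge
    (e.g. monotone separation) are flagged degenerate and never significant.
    """
    candidates = list(candidates)
    shared = [s for s in expr.sample_ids if s in set(survival.sample_ids)]
    if not shared:
        raise ValueError("no samples shared between expression and survival")
    surv = survival.subset(shared)
    if int(surv.event.sum()) < 1:
        raise ValueError("no events in the survival table")
    betas, ps, degen = [], [], []
    for g in candidates:
        x = expr.values.loc[g, shared]
        if np.ptp(x.to_numpy(dtype=float)) == 0:
            betas.append(0.0), ps.append(1.0), degen.append(True)
            continue
        try:
            fit = cox_fit(surv, x.rename(g), ties=ties)
        except _CoxFailure:
            betas.append(0.0), ps.append(1.0), degen.append(True)
            continue
        if not fit.converged:
            betas.append(fit.beta()), ps.append(1.0), degen.append(True)
            continue
        betas.append(fit.beta())
        ps.append(fit.p_value())
        degen.append(False)
    return _stat_table(candidates, betas, ps, degenerate=degen, alpha=alpha)


@dataclass
class PrognosticPair:
    """A gene pair whose within-sample ordering separates survival."""

    gene_a: str
    gene_b: str
    high_risk_order: str          # ordering of the group with HR > 1
    cox_p: float
    hazard_ratio: float           # high-risk group vs low-risk group
    logrank_p: float
    group_sizes: tuple            # (n with Ea<Eb, n with Ea>=Eb)

    def to_signature_pair(self) -> SignaturePair:
        return SignaturePair(self.gene_a, self.gene_b, self.high_risk_order)


@dataclass
class PairScanResult:
    pairs: list = field(default_factory=list)      # significant PrognosticPair
    tested: int = 0
    skipped: list = field(default_factory=list)    # (gene_a, gene_b, reason)


def reo_pair_scan(expr: ExpressionMatrix, survival: SurvivalTable,
                  candidates, alpha: float = 0.05,
                  ties: str = "efron") -> PairScanResult:
    """Scan all unordered candidate pairs for prognosis-associated REOs.

    For each pair (a, b), samples split by the strict within-sample ordering
    Ea < Eb vs not; a univariate Cox on the group indicator gives the pair's
    p-value, and the ordering of the hazard-ratio > 1 group becomes the
    high-risk vote. Pairs whose ordering is constant across samples (one
    group empty) or whose fit degenerates are recorded as skipped.
    """
    candidates = list(candidates)
    if len(candidates) < 2:
        raise ValueError("pair scan needs at least 2 candidate genes")
    shared = [s for s in expr.sample_ids if s in set(survival.sample_ids)]
    surv = survival.subset(shared)
    result = PairScanResult()
    for ga, gb in itertools.combinations(candidates, 2):
        ea = expr.values.loc[ga, shared].to_numpy(dtype=float)
        eb = expr.values.loc[gb, shared].to_numpy(dtype=float)
        a_lt_b = ea < eb                       # strict; ties fall in the a>=b group
        n_lt, n_ge = int(a_lt_b.sum()), int((~a_lt_b).sum())
        if n_lt == 0 or n_ge == 0:
            result.skipped.append((ga, gb, "constant REO (one group empty)"))
            continue
        ind = pd.Series(a_lt_b.astype(float), index=shared, name="a_lt_b")
        try:
            fit = cox_fit(surv, ind, ties=ties)
        except _CoxFailure:
            result.skipped.append((ga, gb, "cox fit failed"))
            continue
        result.tested += 1
        if not fit.converged:
            result.skipped.append((ga, gb, "cox fit did not converge"))
            continue
        beta = fit.beta()
        labels = pd.Series(np.where(a_lt_b, "a<b", "a>b"), index=shared)
        try:
            _, _, lr_p = km_logrank(surv, labels)
        except ValueError:
            lr_p = np.nan
        if fit.p_value() < alpha:
            high_order = "a<b" if beta > 0 else "a>b"
            hr = float(np.exp(abs(beta)))
            result.pairs.append(PrognosticPair(
                gene_a=ga, gene_b=gb, high_risk_order=high_order,
                cox_p=fit.p_value(), hazard_ratio=hr, logrank_p=lr_p,
                group_sizes=(n_lt, n_ge)))
    return result


def assemble_signature(pairs, name: str = "discovered",
                       note: str = "") -> REOSignature:
    """Bundle prognosis-associated pairs into a unanimous-vote REO signature."""
    if not pairs:
        raise ValueError("cannot assemble a signature from zero pairs")
    sig_pairs = [p.to_signature_pair() if isinstance(p, PrognosticPair) else p
                 for p in pairs]
    return REOSignature(pairs=sig_pairs, name=name, note=note)
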