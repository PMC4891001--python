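"""Characterize two prognostic groups across expression, copy number,
mutation, and methylation.

The centerpiece is a two-class Rank Products implementation: each sample is
first reduced to its within-sample gene ranks, and for K pairwise
comparisons between the groups genes are ranked by their rank difference
and summarized by the geometric mean of those cross-comparison ranks.
Working on within-sample ranks (rather than raw fold changes) makes the
statistic exactly invariant to any strictly monotone per-sample transform,
which is the property that lets it tolerate data pooled across experimental
batches. The false-prediction proportion (pFP) is estimated by the
permutation scheme of the original algorithm, with an exact-null mode for
small problems.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as st

from ._stats import bh_qvalues, fisher_two_sided
from .concordance import ConcordanceResult, concordance_binomial
from .io import DiscreteOmicsMatrix, ExpressionMatrix, MethylationMatrix, PPINetwork

__all__ = ["RankProductsResult", "rank_products", "group_frequency_test",
           "direction_imbalance", "cn_expression_correlation",
           "ppi_link_enrichment", "methylation_expression_integration",
           "aggregate_regions", "median_center_batches"]

MAX_PAIRINGS = 100


# ---------------------------------------------------------------------------
# Rank Products


@dataclass
class RankProductsResult:
    """Per-feature Rank Products output.

    ``table`` columns: rp_up, rp_down (geometric mean ranks; rank 1 = most
    deregulated), rank_up, rank_down, pfp_up, pfp_down, direction (+1 up in
    group A, -1 down), sig_up, sig_down.
    """

    table: pd.DataFrame
    n_pairings: int
    n_perm: int
    fdr: float
    pairings_capped: bool = False

    def significant(self, direction: str) -> list:
        col = {"up": "sig_up", "down": "sig_down"}[direction]
        return list(self.table.index[self.table[col]])

    def direction_table(self) -> pd.DataFrame:
        """Signed-statistic view for concordance analyses (statistic = mean
        within-sample-rank difference; its sign is the deregulation
        direction)."""
        return self.table.rename(columns={"mean_diff": "statistic"})[["statistic"]]


def _pairings(group_a, group_b, rng, cap):
    all_pairs = list(itertools.product(range(len(group_a)), range(len(group_b))))
    if len(all_pairs) <= cap:
        return all_pairs, False
    idx = rng.choice(len(all_pairs), size=cap, replace=False)
    return [all_pairs[i] for i in sorted(idx)], True


def _rank_matrix(diffs: np.ndarray) -> np.ndarray:
    """Column-wise ranks, rank 1 = largest difference (most up-regulated)."""
    return st.rankdata(-diffs, axis=0, method="average")


def _exact_null_cdf(n_genes: int, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Exact distribution of a product of k iid uniform ranks on {1..n_genes}.

    Returns (sorted product values, cdf). This is the marginal null of one
    feature under within-comparison rank permutation; by linearity of
    expectation it yields the infinite-permutation limit of the expected
    false-positive count.
    """
    dist = {1.0: 1.0}
    unit = 1.0 / n_genes
    for _ in range(k):
        new: dict = {}
        for prod, p in dist.items():
            for r in range(1, n_genes + 1):
                key = prod * r
                new[key] = new.get(key, 0.0) + p * unit
        if len(new) > 2_000_000:
            raise ValueError("exact null too large; use permutation mode")
        dist = new
    vals = np.array(sorted(dist))
    cdf = np.cumsum([dist[v] for v in vals])
    return vals, cdf


def _pfp_from_expected(expected: np.ndarray, rp: np.ndarray) -> np.ndarray:
    """pFP = expected null count / observed rank, monotonized along the
    RP ordering (a weaker candidate can never have a smaller pFP)."""
    order = np.argsort(rp, kind="stable")
    ranks = np.empty(len(rp))
    ranks[order] = np.arange(1, len(rp) + 1)
    pfp = expected / ranks
    run = np.maximum.accumulate(pfp[order])
    out = np.empty_like(pfp)
    out[order] = run
    return out


def rank_products(values, group_a, group_b, n_perm: int = 100,
                  fdr: float = 0.20, seed: int = 0,
                  max_pairings: int = MAX_PAIRINGS,
                  exact_null: bool = False) -> RankProductsResult:
    """Two-class Rank Products differential analysis with permutation pFP.

    ``values`` is an ExpressionMatrix, MethylationMatrix, or a plain
    genes x samples frame. All |A| x |B| cross-group pairings are used, or a
    seeded random subset of ``max_pairings`` when the product exceeds it.
    ``exact_null=True`` replaces the Monte Carlo pFP with the exact
    infinite-permutation limit (small problems only).
    """
    if isinstance(values, ExpressionMatrix):
        df = values.values
    elif isinstance(values, MethylationMatrix):
        df = values.beta
    elif isinstance(values, pd.DataFrame):
        df = values
    else:
        raise TypeError("values must be an ExpressionMatrix, a "
                        "MethylationMatrix, or a DataFrame")
    group_a, group_b = list(group_a), list(group_b)
    if min(len(group_a), len(group_b)) < 2:
        raise ValueError("each group needs at least 2 samples")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    # within-sample rank transform: the source of monotone-map invariance
    ranked = st.rankdata(df.to_numpy(dtype=float), axis=0, method="average")
    ranked = pd.DataFrame(ranked, index=df.index, columns=df.columns)
    A = ranked[group_a].to_numpy(dtype=float)
    B = ranked[group_b].to_numpy(dtype=float)
    pairs, capped = _pairings(group_a, group_b, rng, max_pairings)
    K = len(pairs)
    n_genes = df.shape[0]

    diffs = np.stack([A[:, i] - B[:, j] for i, j in pairs], axis=1)
    ranks_up = _rank_matrix(diffs)
    ranks_down = _rank_matrix(-diffs)
    log_rp_up = np.log(ranks_up).mean(axis=1)
    log_rp_down = np.log(ranks_down).mean(axis=1)
    rp_up = np.exp(log_rp_up)
    rp_down = np.exp(log_rp_down)

    if exact_null:
        vals, cdf = _exact_null_cdf(n_genes, K)
        def expected(log_rp):
            prod = np.exp(log_rp * K)
            idx = np.searchsorted(vals, prod * (1 + 1e-9), side="right") - 1
            p = np.where(idx >= 0, cdf[np.clip(idx, 0, None)], 0.0)
            return n_genes * p
        exp_up, exp_down = expected(log_rp_up), expected(log_rp_down)
    else:
        null_counts_up = np.zeros(n_genes)
        null_counts_down = np.zeros(n_genes)
        for _ in range(n_perm):
            null_ranks = np.stack(
                [rng.permutation(n_genes) + 1.0 for _ in range(K)], axis=1)
            null_log_rp = np.log(null_ranks).mean(axis=1)
            null_sorted = np.sort(null_log_rp)
            null_counts_up += np.searchsorted(null_sorted,
                                              log_rp_up + 1e-12, side="right")
            null_counts_down += np.searchsorted(null_sorted,
                                                log_rp_down + 1e-12, side="right")
        exp_up = null_counts_up / n_perm
        exp_down = null_counts_down / n_perm

    pfp_up = _pfp_from_expected(exp_up, rp_up)
    pfp_down = _pfp_from_expected(exp_down, rp_down)
    mean_diff = diffs.mean(axis=1)

    order_up = np.empty(n_genes)
    order_up[np.argsort(rp_up, kind="stable")] = np.arange(1, n_genes + 1)
    order_down = np.empty(n_genes)
    order_down[np.argsort(rp_down, kind="stable")] = np.arange(1, n_genes + 1)

    table = pd.DataFrame({
        "rp_up": rp_up, "rp_down": rp_down,
        "rank_up": order_up.astype(int), "rank_down": order_down.astype(int),
        "pfp_up": pfp_up, "pfp_down": pfp_down,
        "mean_diff": mean_diff,
        "direction": np.sign(mean_diff).astype(int),
        "sig_up": pfp_up < fdr, "sig_down": pfp_down < fdr,
    }, index=df.index.rename("feature_id"))
    return RankProductsResult(table=table, n_pairings=K,
                              n_perm=(0 if exact_null else n_perm), fdr=fdr,
                              pairings_capped=capped)


# ---------------------------------------------------------------------------
# frequency comparisons


_EVENTS = {
    "gain": lambda s: s >= 1,
    "loss": lambda s: s <= -1,
    "mutated": lambda s: s == 1,
}


def group_frequency_test(states: DiscreteOmicsMatrix, group_a, group_b,
                         event: str, correction: str = "bh_fdr",
                         threshold: float = 0.20) -> pd.DataFrame:
    """Per-feature two-sided Fisher test of event frequency between groups.

    ``event`` is gain/loss (copy-number mode) or mutated (mutation mode).
    ``correction="bh_fdr"`` flags features at q < threshold (the copy-number
    usage); ``"none"`` flags at raw p < threshold (the mutation usage).
    """
    if event not in _EVENTS:
        raise ValueError(f"event must be one of {sorted(_EVENTS)}")
    if event == "mutated" and states.mode != "mutation":
        raise ValueError("'mutated' event needs a mutation-mode matrix")
    if event in ("gain", "loss") and states.mode != "cn":
        raise ValueError(f"{event!r} event needs a cn-mode matrix")
    group_a, group_b = list(group_a), list(group_b)
    if not group_a or not group_b:
        raise ValueError("both groups must be nonempty")
    ev = _EVENTS[event]
    ca = ev(states.states[group_a]).sum(axis=1).to_numpy()
    cb = ev(states.states[group_b]).sum(axis=1).to_numpy()
    na, nb = len(group_a), len(group_b)
    odds, ps = [], []
    for x, y in zip(ca, cb):
        o, p = fisher_two_sided([[int(x), na - int(x)], [int(y), nb - int(y)]])
        odds.append(o)
        ps.append(p)
    out = pd.DataFrame({
        "count_a": ca, "n_a": na, "count_b": cb, "n_b": nb,
        "freq_a": ca / na, "freq_b": cb / nb,
        "odds_ratio": odds, "fisher_p": ps,
    }, index=states.states.index.rename("feature_id"))
    out["q_value"] = bh_qvalues(out["fisher_p"])
    out["direction"] = np.where(out["freq_a"] >= out["freq_b"], "a", "b")
    if correction == "bh_fdr":
        out["significant"] = out["q_value"] < threshold
    elif correction == "none":
        out["significant"] = out["fisher_p"] < threshold
    else:
        raise ValueError("correction must be 'bh_fdr' or 'none'")
    return out


def direction_imbalance(results: pd.DataFrame) -> ConcordanceResult:
    """Test whether significant features pile up in one group.

    k = number of significant features, s = count in the majority direction,
    tested against Binomial(k, 0.5).
    """
    if len(results) == 0:
        raise ValueError("empty frequency-test results")
    sig = results[results["significant"]]
    k = len(sig)
    if k == 0:
        raise ValueError("no significant features (k = 0)")
    counts = sig["direction"].value_counts()
    return concordance_binomial(k=k, s=int(counts.max()), pe=0.5)


# ---------------------------------------------------------------------------
# copy number vs expression


def cn_expression_correlation(cn: DiscreteOmicsMatrix, expr: ExpressionMatrix,
                              gene_to_region, high_ids, low_ids,
                              fdr: float = 0.20) -> pd.DataFrame:
    """Spearman correlation of per-gene copy-number state with expression.

    Only genes in ``gene_to_region`` (members of the amplified regions) are
    tested; mid-rank ties; BH within the tested set. A gene passes when
    q < fdr, rho > 0, and its mean expression is higher in the high-risk
    group. Constant copy-number genes are excluded with a flag.
    """
    shared = [s for s in expr.sample_ids if s in set(cn.sample_ids)]
    if len(shared) < 5:
        raise ValueError("need at least 5 shared samples")
    high_ids = [s for s in high_ids if s in shared]
    low_ids = [s for s in low_ids if s in shared]
    genes = [g for g in gene_to_region
             if g in set(cn.feature_ids) and g in set(expr.gene_ids)]
    if not genes:
        raise ValueError("no mapped gene present in both matrices")
    rows = []
    for g in genes:
        c = cn.states.loc[g, shared].to_numpy(dtype=float)
        e = expr.values.loc[g, shared].to_numpy(dtype=float)
        if np.ptp(c) == 0:
            rows.append((g, gene_to_region[g], np.nan, np.nan, True, np.nan))
            continue
        rho, p = st.spearmanr(c, e)
        over = expr.values.loc[g, high_ids].mean() > expr.values.loc[g, low_ids].mean()
        rows.append((g, gene_to_region[g], rho, p, False, over))
    out = pd.DataFrame(rows, columns=["gene_id", "region", "spearman_rho", "p_value",
                                      "excluded", "overexpressed_in_high"]
                       ).set_index("gene_id")
    out["q_value"] = bh_qvalues(out["p_value"])
    out["passes"] = (~out["excluded"] & (out["q_value"] < fdr)
                     & (out["spearman_rho"] > 0)
                     & out["overexpressed_in_high"].eq(True))
    return out


# ---------------------------------------------------------------------------
# PPI neighborhood enrichment


@dataclass
class PPIEnrichment:
    """Fraction of query vs background genes with a direct link into a
    reference set, with the two-sided Fisher comparison."""

    table: tuple                 # ((linked_q, unlinked_q), (linked_b, unlinked_b))
    fraction_query: float
    fraction_background: float
    fisher_p: float
    linked_query: list = field(default_factory=list)


def ppi_link_enrichment(net: PPINetwork, query, reference,
                        background) -> PPIEnrichment:
    """Is the query set enriched for direct PPI neighbors of the reference set?

    A gene is "linked" iff it has at least one direct edge to a reference
    gene. ``background`` is the comparison set (disjoint from the query).
    """
    query, reference, background = set(query), set(reference), set(background)
    if not query or not background:
        raise ValueError("query and background must be nonempty")
    if not reference:
        raise ValueError("reference set must be nonempty")
    if query & background:
        raise ValueError("query and background must be disjoint")

    def linked(genes):
        return [g for g in genes if net.neighbors_in(g, reference)]

    lq = linked(query)
    lb = linked(background)
    table = ((len(lq), len(query) - len(lq)),
             (len(lb), len(background) - len(lb)))
    _, p = fisher_two_sided(table)
    return PPIEnrichment(table=table,
                         fraction_query=len(lq) / len(query),
                         fraction_background=len(lb) / len(background),
                         fisher_p=p, linked_query=sorted(lq))


# ---------------------------------------------------------------------------
# methylation / expression integration


def methylation_expression_integration(dmg: RankProductsResult,
                                       deg) -> dict:
    """Concordance of methylation change with opposite expression change.

    ``dmg`` is a Rank Products result on methylation where "up" means
    hypermethylated in the high-risk group. ``deg`` is either a Rank
    Products result on expression or a per-gene statistic table with
    ``significant`` and ``direction`` columns. For each methylation
    direction, k counts its genes that are also DEGs, and s those whose
    expression moved the opposite way (hypermethylated & down-regulated,
    hypomethylated & up-regulated).
    """
    if isinstance(deg, RankProductsResult):
        deg_sig = deg.table[deg.table["sig_up"] | deg.table["sig_down"]]
        deg_dir = deg_sig["direction"]
    else:
        deg_sig = deg[deg["significant"]]
        deg_dir = deg_sig["direction"]
    out = {}
    for meth_dir, expr_sign, key in (("up", -1, "hyper_down"),
                                     ("down", 1, "hypo_up")):
        meth_genes = set(dmg.significant(meth_dir))
        overlap = [g for g in meth_genes if g in deg_sig.index]
        if not overlap:
            raise ValueError(f"no overlap between {meth_dir}-methylated genes "
                             "and DEGs (k = 0)")
        concordant = [g for g in overlap if np.sign(deg_dir[g]) == expr_sign]
        out[key] = {
            "result": concordance_binomial(k=len(overlap), s=len(concordant)),
            "genes": sorted(concordant),
            "overlap": sorted(overlap),
        }
    return out


# ---------------------------------------------------------------------------
# helpers


def aggregate_regions(cn: DiscreteOmicsMatrix, gene_to_region) -> DiscreteOmicsMatrix:
    """Collapse gene-level copy-number calls to region level (cytoband labels)
    by taking the maximum state over member genes (gain-oriented)."""
    genes = [g for g in cn.feature_ids if g in gene_to_region]
    if not genes:
        raise ValueError("no gene maps to a region")
    sub = cn.states.loc[genes]
    regions = pd.Index([gene_to_region[g] for g in genes], name="feature_id")
    return DiscreteOmicsMatrix(sub.groupby(regions, sort=False).max(), mode=cn.mode)


def median_center_batches(expr: ExpressionMatrix, batch: pd.Series) -> ExpressionMatrix:
    """Per-batch, per-gene median centering (a light batch-effect reduction
    applied before cross-batch correlation analyses)."""
    batch = batch.reindex(expr.sample_ids)
    if batch.isna().any():
        raise ValueError("every sample needs a batch label")
    centered = expr.values.copy()
    for b in batch.unique():
        cols = batch.index[batch == b]
        med = centered[cols].median(axis=1)
        centered[cols] = centered[cols].sub(med, axis=0)
    return ExpressionMatrix(centered, expr.scale, expr.sample_annotations,
                            expr.allow_missing)
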