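"""Synthetic cohorts with the statistical structure the analysis assumes.

Four generators emulate the study's input shapes so every downstream stage
is testable without external downloads:

- a two-subtype cell-line panel (resistant vs sensitive) with GI50 drug
  response and planted differentially expressed / GI50-correlated genes;
- a treated patient cohort whose exponential survival hazard depends on the
  planted gene-pair REO votes (proportional hazards by construction);
- a two-group multi-omics arm (copy number, mutation, methylation,
  expression) with planted frequency and coupling differences;
- an Erdos-Renyi PPI background with planted query-reference link excess.

All randomness flows through numpy's default PCG64 generator seeded from the
config; the same seed gives bit-identical outputs. Each generator returns a
manifest of planted truths for test harnesses.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import networkx as nx
import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit

from .io import (DiscreteOmicsMatrix, DrugResponseTable, ExpressionMatrix,
                 GeneSetCollection, MethylationMatrix, PPINetwork, SurvivalTable)

__all__ = ["CellLineArm", "PatientArm", "MultiOmicsArm", "PPIArm",
           "SimulationConfig", "gen_cell_line_cohort", "gen_patient_cohort",
           "gen_multiomics", "gen_ppi", "gen_gene_sets"]

# distinct stream tags so the arms never share a random stream
_TAGS = {"cell": 11, "patient": 22, "omics": 33, "ppi": 44, "sets": 55}


def _rng(seed: int, arm: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), _TAGS[arm]]))


@dataclass
class CellLineArm:
    """Cell-line panel shaped like the study's 28-line 5-FU screen
    (17 resistant, 11 sensitive)."""

    n_genes: int = 2000
    n_resistant: int = 17
    n_sensitive: int = 11
    n_planted_degs: int = 100
    deg_effect: float = 1.5          # mean shift in log2 units (noise sd = 1)
    n_gi50_genes: int = 20           # subset of the planted DEGs
    gi50_correlation: float = 0.8    # target Pearson r against stored GI50
    gi50_group_separation: float = 1.5   # log10 separation of subtype means
    gi50_noise_sd: float = 0.25      # log10 within-subtype spread
    noise_sd: float = 1.0


@dataclass
class PatientArm:
    """Treated patient cohort shaped like the 35-patient discovery set."""

    n_patients: int = 35
    n_genes: int = 500
    planted_pairs: tuple = (("KCNE2", "PRPF3", "a<b"), ("KCNE2", "API5", "a<b"))
    high_risk_prob: float = 24 / 35  # unanimous high-vote probability
    low_risk_all_low_prob: float = 0.7   # P(a low-risk sample votes low on
                                         # every pair); the rest draw a mixed
                                         # non-unanimous pattern
    hazard_ratio: float = 2.78       # unanimous high-risk vs rest
    baseline_hazard: float = 0.03    # events per month in the low-risk group
    censoring_rate: float = 0.3
    follow_up_horizon: float = 60.0  # months, administrative cap
    stage_probs: tuple = (0.20, 0.25, 0.35, 0.20)
    grade_poor_prob: float = 0.6
    male_prob: float = 0.65
    reo_margin: float = 2.0          # log2 gap enforcing the drawn ordering
    anchor_risk_effect: float = 1.5  # log2 down-shift of each pair's first gene
                                     # in unanimous high-risk samples, so the
                                     # pair genes are individually OS-associated
    noise_sd: float = 1.0


@dataclass
class MultiOmicsArm:
    """Two-group multi-omics arm shaped like the TCGA stomach cohort split."""

    n_genes: int = 1000
    genes_per_region: int = 6
    planted_gain_regions: dict = field(default_factory=lambda: {
        r: (0.6, 0.1) for r in ("7p22.1", "7p11.2", "7q21.2", "7q22.1",
                                "13q22.1", "13q12.3", "12p12.1")})
    background_alteration_rate: float = 0.03
    gain_two_copy_prob: float = 0.3
    cn_expression_effect: float = 0.8    # log2 shift per copy gained
    planted_mutation_genes: dict = field(default_factory=lambda: {
        **{f"MUT{i:03d}": (0.05, 0.35) for i in range(20)},  # low-risk-enriched
        "LRP1B": (0.31, 0.15),                               # the one exception
    })
    background_mutation_rate: float = 0.02
    n_hyperm_genes: int = 60
    methylation_shift: float = 1.5       # logit-scale hypermethylation in high group
    methylation_expression_coupling: float = 1.0  # negative coupling strength
    methylation_mu: float = -1.0
    methylation_sd: float = 0.8
    noise_sd: float = 1.0


@dataclass
class PPIArm:
    n_nodes: int = 600
    edge_density: float = 0.01
    planted_link_excess: float = 0.0  # per-query-gene extra-edge probability


@dataclass
class SimulationConfig:
    seed: int = 0
    cell: CellLineArm = field(default_factory=CellLineArm)
    patient: PatientArm = field(default_factory=PatientArm)
    omics: MultiOmicsArm = field(default_factory=MultiOmicsArm)
    ppi: PPIArm = field(default_factory=PPIArm)

    def to_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# cell-line panel


def gen_cell_line_cohort(cfg: SimulationConfig):
    """Simulate the cell-line panel: expression, GI50 table, and a manifest
    naming the planted DEGs and GI50-correlated genes.

    Background genes are iid Normal(mu_g, sd) on the log2 scale. Planted
    DEGs receive an alternating-sign ``deg_effect`` shift in the resistant
    subtype. GI50 is log-normal around subtype means; the first
    ``n_gi50_genes`` planted genes are built as r * z(GI50) +
    sqrt(1-r^2) * noise so their expected Pearson correlation against the
    stored GI50 vector is the configured target.
    """
    arm = cfg.cell
    if arm.n_planted_degs > arm.n_genes:
        raise ValueError("n_planted_degs exceeds n_genes")
    if arm.n_gi50_genes > arm.n_planted_degs:
        raise ValueError("n_gi50_genes must not exceed n_planted_degs")
    rng = _rng(cfg.seed, "cell")
    n = arm.n_resistant + arm.n_sensitive
    cells = [f"CL{i + 1:03d}" for i in range(n)]
    subtype = np.array(["resistant"] * arm.n_resistant
                       + ["sensitive"] * arm.n_sensitive)
    genes = [f"G{i + 1:05d}" for i in range(arm.n_genes)]

    log_gi50 = (np.where(subtype == "resistant",
                         arm.gi50_group_separation / 2,
                         -arm.gi50_group_separation / 2)
                + rng.normal(0, arm.gi50_noise_sd, n))
    gi50 = np.power(10.0, log_gi50)

    mu = rng.uniform(4, 10, arm.n_genes)
    X = mu[:, None] + rng.normal(0, arm.noise_sd, (arm.n_genes, n))
    deg_genes = genes[:arm.n_planted_degs]
    signs = np.where(np.arange(arm.n_planted_degs) % 2 == 0, 1.0, -1.0)
    resistant_mask = (subtype == "resistant").astype(float)

    gi50_genes = deg_genes[:arm.n_gi50_genes]
    sd = gi50.std()
    z = (gi50 - gi50.mean()) / (sd if sd > 0 else 1.0)
    r = arm.gi50_correlation
    for i in range(arm.n_gi50_genes):
        eps = rng.normal(0, 1, n)
        X[i] = mu[i] + signs[i] * arm.noise_sd * (r * z + np.sqrt(1 - r ** 2) * eps)
    for i in range(arm.n_gi50_genes, arm.n_planted_degs):
        X[i] += signs[i] * arm.deg_effect * resistant_mask

    expr = ExpressionMatrix(
        pd.DataFrame(X, index=genes, columns=cells), scale="log2",
        sample_annotations=pd.DataFrame({"subtype": subtype}, index=cells))
    response = DrugResponseTable(pd.Series(gi50, index=cells, name="gi50"),
                                 pd.Series(subtype, index=cells, name="subtype"))
    manifest = {
        "planted_degs": list(deg_genes),
        "planted_gi50_genes": list(gi50_genes),
        "deg_signs": {g: int(s) for g, s in zip(deg_genes, signs)},
        "resistant": [c for c, s in zip(cells, subtype) if s == "resistant"],
        "sensitive": [c for c, s in zip(cells, subtype) if s == "sensitive"],
    }
    return expr, response, manifest


# ---------------------------------------------------------------------------
# patient cohort


def _censoring_horizon(hazards: np.ndarray, target: float, cap: float) -> float:
    """Horizon h of uniform administrative censoring on [0, h] whose expected
    censoring probability under the exponential hazards equals ``target``."""

    def censor_prob(h):
        lam_h = hazards * h
        return float(np.mean((1 - np.exp(-lam_h)) / lam_h)) - target

    lo, hi = 1e-6, cap
    if censor_prob(hi) > 0:       # even the full horizon censors too much
        return cap
    return brentq(censor_prob, lo, hi)


def gen_patient_cohort(cfg: SimulationConfig):
    """Simulate a treated cohort whose hazard depends on planted REO votes.

    Each sample draws an independent high-risk vote per planted pair; the
    unanimous vote sets the hazard to baseline * hazard_ratio. Survival is
    exponential (proportional hazards by construction) with independent
    uniform administrative censoring tuned to the requested censoring rate.
    Expression of the pair genes is laid out to realize the drawn orderings
    with a ``reo_margin`` gap; all other genes are iid background.
    """
    arm = cfg.patient
    if arm.hazard_ratio <= 0:
        raise ValueError("hazard_ratio must be > 0")
    rng = _rng(cfg.seed, "patient")
    n = arm.n_patients
    samples = [f"P{i + 1:04d}" for i in range(n)]
    pair_genes: list = []
    for a, b, _ in arm.planted_pairs:
        for g in (a, b):
            if g not in pair_genes:
                pair_genes.append(g)
    n_bg = arm.n_genes - len(pair_genes)
    if n_bg < 0:
        raise ValueError("n_genes smaller than the planted pair genes")
    bg_genes = [f"B{i + 1:05d}" for i in range(n_bg)]
    genes = pair_genes + bg_genes

    # per-pair votes are drawn through a latent risk label: high-risk samples
    # vote high on every pair; low-risk samples draw one of the non-unanimous
    # vote patterns uniformly (real pair REOs are strongly correlated)
    n_pairs = len(arm.planted_pairs)
    high = rng.random(n) < arm.high_risk_prob
    votes = np.ones((n, n_pairs), dtype=bool)
    low_idx = np.flatnonzero(~high)
    # mixed (non-unanimous, not all-low) patterns: codes 1 .. 2^J - 2
    mixed = np.array([[bool(code >> j & 1) for j in range(n_pairs)]
                      for code in range(1, 2 ** n_pairs - 1)])
    for i in low_idx:
        if len(mixed) == 0 or rng.random() < arm.low_risk_all_low_prob:
            votes[i] = np.zeros(n_pairs, dtype=bool)
        else:
            votes[i] = mixed[rng.integers(len(mixed))]
    hazards = arm.baseline_hazard * np.where(high, arm.hazard_ratio, 1.0)
    T = rng.exponential(1.0 / hazards)
    if arm.censoring_rate <= 0:
        time, event = T, np.ones(n, dtype=int)
        horizon = None
    else:
        horizon = _censoring_horizon(hazards, arm.censoring_rate,
                                     arm.follow_up_horizon)
        C = rng.uniform(0, horizon, n)
        event = (T <= C).astype(int)
        time = np.minimum(T, C)

    mu = rng.uniform(4, 10, len(genes))
    X = mu[:, None] + rng.normal(0, arm.noise_sd, (len(genes), n))
    # anchor genes (each pair's gene_a) shift down in high-risk samples so the
    # individual genes, not only the orderings, carry survival signal
    anchors = dict.fromkeys(a for a, _, _ in arm.planted_pairs)
    for a in anchors:
        X[genes.index(a)] -= arm.anchor_risk_effect * high.astype(float)
    # realize each drawn ordering: gene_b is placed relative to gene_a
    for j, (a, b, order) in enumerate(arm.planted_pairs):
        ia, ib = genes.index(a), genes.index(b)
        gap = arm.reo_margin + np.abs(rng.normal(0, 0.25, n))
        high_vote = votes[:, j]
        want_a_lt_b = high_vote if order == "a<b" else ~high_vote
        X[ib] = X[ia] + np.where(want_a_lt_b, gap, -gap)

    stage = rng.choice(["I", "II", "III", "IV"], size=n, p=arm.stage_probs)
    grade = np.where(rng.random(n) < arm.grade_poor_prob,
                     "poor/undifferentiated", "moderate")
    gender = np.where(rng.random(n) < arm.male_prob, "male", "female")

    expr = ExpressionMatrix(pd.DataFrame(X, index=genes, columns=samples),
                            scale="log2")
    surv = SurvivalTable(pd.DataFrame({
        "time": time, "event": event, "stage": stage, "grade": grade,
        "gender": gender}, index=pd.Index(samples, name="sample_id")))
    manifest = {
        "planted_pairs": [list(p) for p in arm.planted_pairs],
        "true_risk": {s: ("high" if h else "low") for s, h in zip(samples, high)},
        "pair_votes": {s: [bool(v) for v in row]
                       for s, row in zip(samples, votes)},
        "censoring_horizon": horizon,
        "hazard_ratio": arm.hazard_ratio,
    }
    return expr, surv, manifest


# ---------------------------------------------------------------------------
# multi-omics arm


def gen_multiomics(cfg: SimulationConfig, risk_labels: pd.Series):
    """Simulate CN, mutation, methylation and expression for two risk groups.

    Copy-number gains are planted region-wise (all member genes share the
    region's per-sample event) with group-specific probabilities; expression
    of gained genes rises with copy dosage so CN-expression correlation is
    recoverable. Mutations are per-gene Bernoulli with group-specific
    probabilities. Methylation is logit-normal with a planted
    hypermethylation shift in the high-risk group, and the expression of
    those genes is coupled negatively with the configured strength. Every
    unplanted feature is exchangeable between groups.
    """
    arm = cfg.omics
    labels = risk_labels.astype(str)
    high = list(labels.index[labels == "high"])
    low = list(labels.index[labels == "low"])
    if not high or not low:
        raise ValueError("both risk groups must be nonempty")
    rng = _rng(cfg.seed, "omics")
    samples = list(labels.index)
    n = len(samples)
    is_high = labels.reindex(samples).eq("high").to_numpy()

    # --- copy number, region-structured
    gene_to_region = {}
    for region in arm.planted_gain_regions:
        for k in range(arm.genes_per_region):
            gene_to_region[f"CNG_{region}_{k + 1}"] = region
    cn_genes = list(gene_to_region)
    mut_genes = list(arm.planted_mutation_genes)
    n_named = len(cn_genes) + len(mut_genes) + arm.n_hyperm_genes
    if n_named > arm.n_genes:
        raise ValueError("n_genes too small for the planted feature sets")
    hyper_genes = [f"METH{i + 1:04d}" for i in range(arm.n_hyperm_genes)]
    bg_genes = [f"OM{i + 1:05d}" for i in range(arm.n_genes - n_named)]
    genes = cn_genes + mut_genes + hyper_genes + bg_genes

    cn = np.zeros((len(genes), n), dtype=int)
    rare = rng.random((len(genes), n))
    cn[rare < arm.background_alteration_rate / 2] = -1
    cn[(rare >= arm.background_alteration_rate / 2)
       & (rare < arm.background_alteration_rate)] = 1
    for region, (p_high, p_low) in arm.planted_gain_regions.items():
        p = np.where(is_high, p_high, p_low)
        gained = rng.random(n) < p
        amp = np.where(rng.random(n) < arm.gain_two_copy_prob, 2, 1)
        state = np.where(gained, amp, 0)
        for g in cn_genes:
            if gene_to_region[g] == region:
                cn[genes.index(g)] = state

    # --- mutation
    mut = (rng.random((len(genes), n)) < arm.background_mutation_rate).astype(int)
    for g, (p_high, p_low) in arm.planted_mutation_genes.items():
        p = np.where(is_high, p_high, p_low)
        mut[genes.index(g)] = (rng.random(n) < p).astype(int)

    # --- methylation (logit-normal), hypermethylated in the high-risk group
    lg = rng.normal(arm.methylation_mu, arm.methylation_sd, (len(genes), n))
    for g in hyper_genes:
        lg[genes.index(g)] += arm.methylation_shift * is_high
    beta = expit(lg)

    # --- expression coupled to CN dosage and (negatively) to methylation
    mu = rng.uniform(4, 10, len(genes))
    X = mu[:, None] + rng.normal(0, arm.noise_sd, (len(genes), n))
    X += arm.cn_expression_effect * cn
    coupling = arm.methylation_expression_coupling
    if coupling != 0:
        for g in hyper_genes:
            i = genes.index(g)
            X[i] -= coupling * (lg[i] - arm.methylation_mu)

    idx = pd.Index(genes, name="feature_id")
    cols = pd.Index(samples, name="sample_id")
    out = (
        DiscreteOmicsMatrix(pd.DataFrame(cn, index=idx, columns=cols), mode="cn"),
        DiscreteOmicsMatrix(pd.DataFrame(mut, index=idx, columns=cols),
                            mode="mutation"),
        MethylationMatrix(pd.DataFrame(beta, index=idx, columns=cols)),
        ExpressionMatrix(pd.DataFrame(X, index=idx, columns=cols), scale="log2"),
    )
    manifest = {
        "gene_to_region": gene_to_region,
        "planted_gain_regions": {r: list(p) for r, p in
                                 arm.planted_gain_regions.items()},
        "planted_mutation_genes": {g: list(p) for g, p in
                                   arm.planted_mutation_genes.items()},
        "hypermethylated_genes": hyper_genes,
        "high": high, "low": low,
    }
    return (*out, manifest)


# ---------------------------------------------------------------------------
# PPI


def gen_ppi(cfg: SimulationConfig, query_set, reference_set, extra_nodes=()):
    """Erdos-Renyi PPI background plus planted query-reference link excess.

    Each query gene gains an extra edge to a uniformly chosen reference gene
    with probability ``planted_link_excess`` on top of the background
    density. ``extra_nodes`` (e.g. the comparison background gene set) join
    the random graph without any planted excess.
    """
    arm = cfg.ppi
    if not 0 < arm.edge_density < 1:
        raise ValueError("edge_density must lie in (0, 1)")
    rng = _rng(cfg.seed, "ppi")
    query, reference = list(dict.fromkeys(query_set)), list(dict.fromkeys(reference_set))
    named = list(dict.fromkeys(query + reference + list(extra_nodes)))
    n_extra = max(arm.n_nodes - len(named), 0)
    nodes = named + [f"PPI{i + 1:05d}" for i in range(n_extra)]
    g = nx.gnp_random_graph(len(nodes), arm.edge_density,
                            seed=int(rng.integers(2 ** 31)))
    g = nx.relabel_nodes(g, dict(enumerate(nodes)))
    if arm.planted_link_excess > 0:
        for q in query:
            if rng.random() < arm.planted_link_excess:
                g.add_edge(q, reference[int(rng.integers(len(reference)))])
    g.remove_edges_from(nx.selfloop_edges(g))
    return PPINetwork(g)


# ---------------------------------------------------------------------------
# gene sets


def gen_gene_sets(cfg: SimulationConfig, universe, n_sets: int = 20,
                  set_size: int = 25, planted_query=None,
                  planted_fraction: float = 0.6) -> GeneSetCollection:
    """Random gene-set collection over ``universe`` with one optional planted
    pathway drawing ``planted_fraction`` of its members from a query set."""
    rng = _rng(cfg.seed, "sets")
    universe = list(universe)
    sets = {}
    for i in range(n_sets):
        members = rng.choice(universe, size=min(set_size, len(universe)),
                             replace=False)
        sets[f"PW{i + 1:03d}"] = (f"pathway_{i + 1}", set(members))
    if planted_query:
        pq = list(planted_query)
        k = min(int(round(set_size * planted_fraction)), len(pq))
        members = set(rng.choice(pq, size=k, replace=False))
        rest = [u for u in universe if u not in members]
        members |= set(rng.choice(rest, size=set_size - k, replace=False))
        sets["PW_PLANTED"] = ("planted_pathway", members)
    return GeneSetCollection(sets)
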