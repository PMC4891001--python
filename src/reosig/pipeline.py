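"""End-to-end orchestration: simulate -> discover -> classify -> survival ->
multi-omics -> enrichment.

The flow mirrors the study design: a drug-screened cell-line panel seeds the
candidate funnel (DEGs between resistant and sensitive lines, then
GI50-correlated genes), a treated patient cohort narrows it to OS-associated
genes and yields the REO pair signature, the signature classifies an
independent multi-omics cohort, and the two risk groups are characterized
across copy number, mutation, methylation and pathways. Every stage writes a
stable filename under the output directory and contributes counts to a run
manifest so the funnel is auditable.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as rio
from .classify import classify_cohort
from .discovery import (assemble_signature, deg_ttest, gi50_correlation_filter,
                        os_association_filter, reo_pair_scan)
from .enrich import hypergeom_enrichment
from .multiomics import (cn_expression_correlation, direction_imbalance,
                         group_frequency_test, methylation_expression_integration,
                         ppi_link_enrichment, rank_products, aggregate_regions)
from .simulate import (SimulationConfig, gen_cell_line_cohort, gen_gene_sets,
                       gen_multiomics, gen_patient_cohort, gen_ppi)
from .survival import clinical_design, cox_fit, km_logrank

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Thresholds (the study's printed defaults) plus simulation settings."""

    seed: int = 0
    outdir: str = "pipeline_out"
    deg_fdr: float = 0.20
    gi50_fdr: float = 0.20
    cox_alpha: float = 0.05
    pair_alpha: float = 0.05
    rp_fdr: float = 0.20
    cn_fdr: float = 0.20
    mut_alpha: float = 0.05
    enrich_fdr: float = 0.10
    n_validation_patients: int = 150   # independent cohort for the omics arm
    simulation: SimulationConfig | None = None

    def __post_init__(self) -> None:
        for name in ("deg_fdr", "gi50_fdr", "cox_alpha", "pair_alpha", "rp_fdr",
                     "cn_fdr", "mut_alpha", "enrich_fdr"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        if self.simulation is None:
            self.simulation = SimulationConfig(seed=self.seed)


def _round_floats(obj, ndigits=10):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    return obj


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage in order and return (and write) the run manifest."""
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    sim = cfg.simulation
    manifest: dict = {"seed": cfg.seed,
                      "thresholds": {k: getattr(cfg, k) for k in
                                     ("deg_fdr", "gi50_fdr", "cox_alpha",
                                      "pair_alpha", "rp_fdr", "cn_fdr",
                                      "mut_alpha", "enrich_fdr")}}

    # --- stage 1: simulate the cell-line panel and discovery cohort
    cell_expr, gi50, cell_truth = gen_cell_line_cohort(sim)
    # alias the first planted GI50 genes to the signature pair genes so the
    # panel and the patient cohorts share the candidate namespace
    pair_genes = []
    for a, b, _ in sim.patient.planted_pairs:
        for g in (a, b):
            if g not in pair_genes:
                pair_genes.append(g)
    gi50_genes = cell_truth["planted_gi50_genes"]
    if len(gi50_genes) < len(pair_genes):
        raise ValueError("cell arm needs at least as many GI50 genes as "
                         "signature pair genes")
    alias = dict(zip(gi50_genes, pair_genes))
    cell_expr.values.rename(index=alias, inplace=True)
    rio.write_matrix_tsv(cell_expr, out / "cell_expression.tsv")
    rio.write_drug_response_tsv(gi50, out / "cell_gi50.tsv")

    pat_expr, pat_surv, pat_truth = gen_patient_cohort(sim)
    rio.write_matrix_tsv(pat_expr, out / "patient_expression.tsv")
    rio.write_survival_tsv(pat_surv, out / "patient_survival.tsv")

    # --- stage 2: the discovery funnel
    try:
        degs = deg_ttest(cell_expr, cell_truth["resistant"],
                         cell_truth["sensitive"], fdr=cfg.deg_fdr)
    except Exception as exc:
        raise RuntimeError(f"stage 'discovery/deg_ttest' failed on the "
                           f"cell-line matrix {cell_expr.shape}: {exc}") from exc
    deg_list = list(degs.index[degs["significant"]])
    corr = gi50_correlation_filter(cell_expr, gi50, deg_list, fdr=cfg.gi50_fdr)
    gi50_hits = list(corr.index[corr["significant"]])
    candidates = [g for g in gi50_hits if g in set(pat_expr.gene_ids)]
    os_tab = os_association_filter(pat_expr, pat_surv, candidates,
                                   alpha=cfg.cox_alpha)
    os_genes = list(os_tab.index[os_tab["significant"]])
    scan = reo_pair_scan(pat_expr, pat_surv, os_genes, alpha=cfg.pair_alpha) \
        if len(os_genes) >= 2 else None
    pairs = scan.pairs if scan else []
    manifest["funnel"] = {
        "n_genes": cell_expr.shape[0], "n_degs": len(deg_list),
        "n_gi50_genes": len(gi50_hits), "n_candidates_on_platform": len(candidates),
        "n_os_genes": len(os_genes), "n_pairs": len(pairs),
        "pairs": [[p.gene_a, p.gene_b, p.high_risk_order] for p in pairs],
    }
    for tab, name in ((degs, "degs.tsv"), (corr, "gi50_correlation.tsv"),
                      (os_tab, "os_association.tsv")):
        tab.to_csv(out / name, sep="\t")
    if not pairs:
        manifest["status"] = "no signature pairs found"
        _write_manifest(manifest, out)
        return manifest
    signature = assemble_signature(pairs, name="discovered",
                                   note=f"seed={cfg.seed}")
    signature.to_json(out / "signature.json")

    # --- stage 3: classify the discovery cohort and test survival separation
    calls = classify_cohort(pat_expr, signature)
    calls.to_csv(out / "risk_calls.tsv", sep="\t")
    labels = calls["label"]
    _, chi2, lr_p = km_logrank(pat_surv, labels)
    uni = cox_fit(pat_surv, clinical_design(pat_surv, risk_labels=labels))
    multi = cox_fit(pat_surv, clinical_design(pat_surv, risk_labels=labels,
                                              multivariate=True))
    manifest["survival"] = {
        "n_high": int((labels == "high").sum()),
        "n_low": int((labels == "low").sum()),
        "logrank_chi2": chi2, "logrank_p": lr_p,
        "univariate_hr": uni.hazard_ratio("high_risk"),
        "univariate_p": uni.p_value("high_risk"),
        "multivariate_hr": multi.hazard_ratio("high_risk"),
        "multivariate_p": multi.p_value("high_risk"),
    }

    # --- stage 4: classify an independent cohort and characterize the groups
    val_sim = dataclasses.replace(
        sim, seed=sim.seed + 1000003,
        patient=dataclasses.replace(sim.patient,
                                    n_patients=cfg.n_validation_patients))
    val_expr, val_surv, _ = gen_patient_cohort(val_sim)
    val_calls = classify_cohort(val_expr, signature)
    val_labels = val_calls["label"]
    high = list(val_labels.index[val_labels == "high"])
    low = list(val_labels.index[val_labels == "low"])
    manifest["validation"] = {"n_high": len(high), "n_low": len(low)}
    if high and low:
        _, vchi2, vlr_p = km_logrank(val_surv, val_labels)
        manifest["validation"].update({"logrank_chi2": vchi2, "logrank_p": vlr_p})

    cn, mut, meth, om_expr, om_truth = gen_multiomics(val_sim, val_labels)
    for m, name in ((cn, "cn_states.tsv"), (mut, "mutations.tsv"),
                    (meth, "methylation.tsv"), (om_expr, "omics_expression.tsv")):
        rio.write_matrix_tsv(m, out / name)

    regions = aggregate_regions(cn, om_truth["gene_to_region"])
    cn_freq = group_frequency_test(regions, high, low, event="gain",
                                   correction="bh_fdr", threshold=cfg.cn_fdr)
    cn_freq.to_csv(out / "cn_region_frequencies.tsv", sep="\t")
    gained = list(cn_freq.index[cn_freq["significant"]
                                & (cn_freq["direction"] == "a")])
    genes_in_gained = {g: r for g, r in om_truth["gene_to_region"].items()
                       if r in gained}
    cn_corr = (cn_expression_correlation(cn, om_expr, genes_in_gained, high,
                                         low, fdr=cfg.cn_fdr)
               if genes_in_gained else pd.DataFrame())
    amplified_overexpressed = (list(cn_corr.index[cn_corr["passes"]])
                               if len(cn_corr) else [])

    mut_freq = group_frequency_test(mut, high, low, event="mutated",
                                    correction="none", threshold=cfg.mut_alpha)
    mut_freq.to_csv(out / "mutation_frequencies.tsv", sep="\t")
    imbalance = None
    if mut_freq["significant"].any():
        imbalance = direction_imbalance(mut_freq)

    dmg = rank_products(meth, high, low, n_perm=50, fdr=cfg.rp_fdr,
                        seed=cfg.seed + 7)
    deg_om = rank_products(om_expr, high, low, n_perm=50, fdr=cfg.rp_fdr,
                           seed=cfg.seed + 8)
    try:
        meth_integration = methylation_expression_integration(dmg, deg_om)
        hyper_down = meth_integration["hyper_down"]
        meth_summary = {
            "k": hyper_down["result"].k, "s": hyper_down["result"].s,
            "score": hyper_down["result"].score,
            "p": hyper_down["result"].p_value,
        }
        hyper_down_genes = hyper_down["genes"]
    except ValueError:
        meth_summary, hyper_down_genes = {"k": 0}, []

    manifest["multiomics"] = {
        "gained_regions": gained,
        "n_amplified_overexpressed": len(amplified_overexpressed),
        "n_differential_mutation_genes": int(mut_freq["significant"].sum()),
        "mutation_direction_imbalance": (
            {"k": imbalance.k, "s": imbalance.s, "p": imbalance.p_value}
            if imbalance else None),
        "hypermethylation_downregulation": meth_summary,
    }

    # --- stage 5: PPI neighborhood of the amplified-overexpressed genes
    reference = [f"FUMET{i + 1:03d}" for i in range(30)]
    query = amplified_overexpressed or list(genes_in_gained)
    background = [g for g in om_expr.gene_ids if g not in set(query)]
    if query:
        net = gen_ppi(val_sim, query, reference, extra_nodes=background)
        ppi = ppi_link_enrichment(net, query, reference, background)
        manifest["ppi"] = {"table": [list(r) for r in ppi.table],
                           "fraction_query": ppi.fraction_query,
                           "fraction_background": ppi.fraction_background,
                           "fisher_p": ppi.fisher_p}

    # --- stage 6: pathway enrichment of the hypermethylation-downregulated genes
    universe = list(om_expr.gene_ids)
    query = hyper_down_genes or list(dmg.significant("up"))
    if query:
        sets = gen_gene_sets(val_sim, universe, planted_query=query)
        enr = hypergeom_enrichment(query, sets, universe, fdr=cfg.enrich_fdr)
        enr.to_csv(out / "enrichment.tsv", sep="\t")
        manifest["enrichment"] = {
            "n_significant": int(enr["significant"].sum()),
            "top_pathway": enr.index[0], "top_p": float(enr["p_value"].iloc[0]),
        }

    manifest["status"] = "ok"
    _write_manifest(manifest, out)
    return manifest


def _write_manifest(manifest: dict, out: Path) -> None:
    (out / "manifest.json").write_text(
        json.dumps(_round_floats(manifest), indent=2, sort_keys=True) + "\n")
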