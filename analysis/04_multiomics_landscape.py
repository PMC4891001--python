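#!/usr/bin/env python
"""Characterize the risk groups of an independent multi-omics cohort:
copy-number gain frequencies per region, CN-expression correlation,
mutation frequency imbalance, hypermethylation-with-downregulation
concordance, PPI neighborhood enrichment, and pathway over-representation.
"""

import json
from pathlib import Path

import pandas as pd

from reosig.classify import REOSignature, classify_cohort
from reosig.enrich import hypergeom_enrichment
from reosig.multiomics import (aggregate_regions, cn_expression_correlation,
                               direction_imbalance, group_frequency_test,
                               methylation_expression_integration,
                               ppi_link_enrichment, rank_products)
from reosig.simulate import (PPIArm, PatientArm, SimulationConfig,
                             gen_gene_sets, gen_multiomics, gen_patient_cohort,
                             gen_ppi)

SEED = 0
BASE = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    # an independent cohort classified by the discovered signature; the PPI
    # arm plants extra links between the amplified genes and the reference set
    sim = SimulationConfig(seed=SEED + 1000003,
                           patient=PatientArm(n_patients=150),
                           ppi=PPIArm(planted_link_excess=0.6))
    expr, _, _ = gen_patient_cohort(sim)
    sig = REOSignature.from_json(BASE / "signature.json")
    labels = classify_cohort(expr, sig)["label"]
    high = list(labels.index[labels == "high"])
    low = list(labels.index[labels == "low"])
    print(f"independent cohort: {len(high)} high / {len(low)} low")

    cn, mut, meth, om_expr, truth = gen_multiomics(sim, labels)

    regions = aggregate_regions(cn, truth["gene_to_region"])
    cn_freq = group_frequency_test(regions, high, low, event="gain",
                                   correction="bh_fdr", threshold=0.20)
    cn_freq.to_csv(BASE / "cn_region_frequencies.tsv", sep="\t")
    gained = list(cn_freq.index[cn_freq["significant"]
                                & (cn_freq["direction"] == "a")])
    print(f"regions gained more often in high-risk (FDR < 20%): {gained}")

    genes_in_gained = {g: r for g, r in truth["gene_to_region"].items()
                       if r in gained}
    cn_corr = cn_expression_correlation(cn, om_expr, genes_in_gained,
                                        high, low, fdr=0.20)
    amplified = list(cn_corr.index[cn_corr["passes"]])
    print(f"{len(amplified)} amplified genes overexpressed in high-risk "
          f"(Spearman, FDR < 20%)")

    mut_freq = group_frequency_test(mut, high, low, event="mutated",
                                    correction="none", threshold=0.05)
    mut_freq.to_csv(BASE / "mutation_frequencies.tsv", sep="\t")
    imb = direction_imbalance(mut_freq)
    majority = "low" if imb.s > imb.k / 2 else "high"
    print(f"mutation frequencies: {imb.k} differential genes, {imb.s} higher "
          f"in the {majority}-risk group (binomial P = {imb.p_value:.3g})")

    dmg = rank_products(meth, high, low, n_perm=100, fdr=0.20, seed=SEED + 7)
    deg = rank_products(om_expr, high, low, n_perm=100, fdr=0.20, seed=SEED + 8)
    integ = methylation_expression_integration(dmg, deg)["hyper_down"]
    res = integ["result"]
    print(f"hypermethylation vs down-regulation: k = {res.k}, s = {res.s}, "
          f"score = {100 * res.score:.2f}%, P = {res.p_value:.3g}")

    reference = [f"FUMET{i + 1:03d}" for i in range(30)]
    background = [g for g in om_expr.gene_ids if g not in set(amplified)]
    net = gen_ppi(sim, amplified, reference, extra_nodes=background)
    ppi = ppi_link_enrichment(net, amplified, reference, background)
    print(f"PPI direct links to reference set: {100 * ppi.fraction_query:.2f}% "
          f"of amplified vs {100 * ppi.fraction_background:.2f}% background "
          f"(Fisher P = {ppi.fisher_p:.3g})")

    universe = list(om_expr.gene_ids)
    sets = gen_gene_sets(sim, universe, planted_query=integ["genes"])
    enr = hypergeom_enrichment(integ["genes"], sets, universe, fdr=0.10)
    enr.to_csv(BASE / "enrichment.tsv", sep="\t")
    top = enr.iloc[0]
    print(f"top enriched pathway: {top.name} (overlap {top['overlap']}/"
          f"{top['pathway_size']}, q = {top['q_value']:.3g})")


if __name__ == "__main__":
    main()
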