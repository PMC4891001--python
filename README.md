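# reosig

Rank-based gene-pair prognostic signatures for gastric cancer patients
treated with 5-Fluorouracil (5-FU)-based chemotherapy, together with the
downstream survival, concordance, and multi-omics analyses that
characterize the resulting risk groups.

## The problem and the method

Risk-score expression signatures do not transfer between laboratories:
their thresholds shift with normalization and batch effects. A signature
built on **within-sample relative expression orderings (REOs)** avoids the
problem entirely — it only asks, inside one sample, whether gene *a* is
expressed above or below gene *b*. Any strictly monotone per-sample
transform (normalization, log choice, scanner drift) leaves every ordering,
and therefore every call, unchanged.

The package implements the full discovery-to-application flow:

1. **Candidate funnel** — differentially expressed genes between
   5-FU-resistant and 5-FU-sensitive cell lines (Student's *t*, BH
   FDR < 20%); of those, genes Pearson-correlated with 5-FU GI₅₀ (FDR < 20%,
   adjusted within the candidate set); of those, genes associated with
   overall survival in a treated cohort (univariate Cox, *P* < 0.05).
2. **REO pair scan** — for every unordered pair (*a*, *b*) of surviving
   genes, samples split by *Eₐ* < *E_b* vs *Eₐ* > *E_b*; pairs whose split
   separates survival (Cox *P* < 0.05) enter the signature. A sample is
   called **high risk iff every pair votes high risk** (unanimous vote).
   The packaged default signature is the published two-pair rule: high risk
   iff KCNE2 is expressed below both PRPF3 and API5.
3. **Group characterization** — Kaplan–Meier/log-rank and Cox
   (uni/multivariate, Efron ties); Rank Products differential analysis on
   within-sample ranks (batch-insensitive) for expression and methylation;
   Fisher tests of copy-number-gain and mutation frequencies; Spearman
   CN–expression correlation; direct-link PPI enrichment; hypergeometric
   pathway over-representation (FDR < 10%).
4. **Concordance statistic** — for two analyses that each assign a
   direction to *k* shared genes, of which *s* agree, the score is *s*/*k*
   and its significance the upper binomial tail
   *P* = P(X ≥ s), X ~ Binomial(k, Pe = 0.5).

A seeded synthetic-data module generates every input shape the analyses
need — a two-subtype cell-line panel with GI₅₀, survival cohorts whose
exponential hazard follows planted gene-pair REOs, two-group CN/mutation/
methylation matrices with planted differences, and PPI graphs with planted
link excess — so the whole flow is testable without downloads.

## Worked example

The numbered drivers under `analysis/` run the whole flow on synthetic data
(seed 0, a 28-line cell panel and a 200-patient cohort) and write their
tables under `results/`:

```sh
python analysis/01_simulate_cohorts.py
python analysis/02_discover_signature.py
```

prints

```
funnel: 2000 genes -> 111 DEGs -> 107 GI50-correlated -> 3 on platform -> 3 OS-associated -> 2 pairs
  pair KCNE2/PRPF3: high risk if a<b, Cox P = 5.86e-07, HR = 3.07
  pair KCNE2/API5: high risk if a<b, Cox P = 1.76e-05, HR = 2.55
recovered planted pairs exactly
```

i.e. the funnel narrowed 2,000 genes to the two planted pairs, each with
the planted high-risk ordering. `analysis/03_classify_and_survival.py` then
classifies the cohort with the discovered signature and tests the split:

```
classified 137 high-risk / 63 low-risk
log-rank: chi2 = 36.13, P = 1.85e-09
univariate Cox: HR = 3.38 (95% CI 2.23-5.12), P = 9.28e-09
```

The high-risk group carries a ~3-fold hazard, close to the planted hazard
ratio. `analysis/04_multiomics_landscape.py` characterizes an independent
classified cohort (all seven planted gain regions recovered at FDR < 20%;
35/35 differential mutation genes higher in the low-risk group,
*P* = 2.9e-11; hypermethylation-with-downregulation concordance 93.75%),
and `analysis/05_printed_statistics.py` recomputes the exact desk-scale
statistics (e.g. concordance 14/14 → *P* = 6.10e-05).

The same stages are available as a CLI (`reosig simulate | discover |
classify | survival | concordance | multiomics | enrich | run-all`), e.g.

```sh
reosig concordance --k 14 --s 14
# k = 14, s = 14, score = 100.00%, P = 6.104e-05
```

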