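# Methods

## The REO signature model

A relative expression ordering (REO) signature is a list of gene pairs
(*a*, *b*), each annotated with the ordering that votes "high risk"
(*Eₐ* < *E_b* or *Eₐ* > *E_b*). Classification reads only within-sample
orderings under strict inequality — a tie never votes high risk — and a
sample is high risk iff **all** pairs vote high (unanimous vote). Because a
strictly monotone per-sample transform preserves every within-sample
ordering, calls are invariant to normalization, log choice, and additive
per-sample shifts; this is the property that lets a fixed signature be
applied to single samples from any laboratory. The packaged default is the
published two-pair gastric cancer rule (high risk iff KCNE2 below both
PRPF3 and API5), shipped as a versioned JSON asset. Missing signature genes
are a hard error by default: silently classifying on a partial signature
changes the rule's meaning (an explicit `missing="low"` policy is
available and flags the downgrade).

## Discovery funnel

- **DEG stage** — per-gene two-sided *t*-test between resistant and
  sensitive cell lines. Welch's unequal-variance form is the default
  (microarray group variances are rarely equal); a pooled-variance option
  exists and is what the closed-form unit test checks. Genes with zero
  variance in both groups are flagged degenerate with *p* = 1.
- **GI₅₀ stage** — Pearson correlation of each DEG against the stored GI₅₀
  values (no transform is applied to GI₅₀; correlation runs on the stored
  scale). BH adjustment runs **within the candidate set only**: this
  pre-selection is what makes FDR < 20% attainable on a 28-line panel —
  genome-wide adjustment at that sample size leaves nothing.
- **OS stage** — univariate Cox on continuous expression; genes whose fit
  fails or separates monotonically are excluded with a flag, never
  silently kept.
- **Pair scan** — every unordered pair of survivors; the Cox covariate is
  the REO indicator (Eₐ < E_b), and the ordering of the hazard-ratio > 1
  group becomes the pair's high-risk vote. The log-rank *p* is computed
  alongside for reporting. Pairs with a constant ordering (one group
  empty) are recorded as skipped.

Multiple testing is Benjamini–Hochberg wherever an FDR threshold appears.
Thresholds default to the study's printed values: DEG FDR 0.20, GI₅₀ FDR
0.20, Cox α 0.05, Rank Products FDR 0.20, CN FDR 0.20, mutation α 0.05,
enrichment FDR 0.10.

## Survival statistics

Kaplan–Meier curves and the log-rank test come from lifelines; the Cox
model uses lifelines' Efron tie handling by default (less biased than
Breslow under ties). A self-contained Breslow Newton–Raphson
partial-likelihood solver is included for cross-checking — the two schemes
must agree exactly on tie-free data, and the suite asserts this against an
independent Newton oracle. Wald 95% intervals throughout; the multivariate
model uses the conventional reference coding (low-risk, stage I–II,
moderate grade, female). Non-convergence and monotone separation produce a
flagged result (`converged=False`), never a silent estimate.

## Concordance statistic

For *k* comparable genes of which *s* agree in direction, the score is
*s*/*k* and its significance the upper binomial tail
P(X ≥ s), X ~ Binomial(k, Pe), evaluated through the regularized
incomplete beta (scipy's survival function), which stays accurate for
k up to 1e5 and tails far below 1e-300. Pe is fixed at 0.5. Three direction
modes are provided: same-sign DEG agreement; GI₅₀-vs-OS (a gene whose
expression tracks resistance, r > 0, should carry higher hazard, β > 0 —
"positively correlated with GI₅₀, negatively with prognosis" is
operationalized as sign(r) = sign(β) since worse prognosis means a larger
log-hazard); and methylation-vs-expression, where opposite signs are
concordant. The tail is P(X ≥ s); the complementary lower sum uses the
exponent (1 − Pe)^(k−i) so the terms form a probability mass and
P(k, 0) = 1.

## Rank Products

Two-class Rank Products with one deliberate variant: **each sample is first
reduced to its within-sample gene ranks**, and the K cross-group
comparisons rank genes by their rank difference. The original algorithm
ranks raw fold changes, which is *not* invariant under per-sample monotone
maps; computing on within-sample ranks makes the batch-insensitivity
property exact, which this package treats as the method's defining
guarantee (the suite asserts bit-identical output under 100 random
monotone maps). Pairings are the full |A|×|B| product, capped at 100
seeded random pairings. RP is the geometric mean of the cross-comparison
ranks; the false-prediction proportion (pFP) follows the permutation
scheme (within-comparison rank permutation, default 100 permutations):
pFP(g) = E[null features at or below RP(g)] / rank(g), monotonized along
the RP ordering so a weaker candidate can never have a smaller pFP.

An **exact-null mode** replaces the Monte Carlo estimate with the
infinite-permutation limit: one feature's null ranks are iid uniform on
{1..G} across comparisons, and by linearity of expectation the expected
null count is G · P(∏ᵢ Uᵢ ≤ RPᵏ), computed by dynamic programming over
exact product values. The suite checks this against brute-force
enumeration of all Gᵏ rank combinations on a 5-gene, 3-vs-3 toy problem,
and checks that the Monte Carlo mode converges to it.

## Multi-omics comparisons

Copy-number events are GISTIC-style calls: gain = state ≥ +1, loss =
state ≤ −1; region-level state is the maximum over member genes (the
aggregation rule is a package choice; region membership is a supplied
table, not computed from coordinates). Frequency comparisons are two-sided
Fisher tests — two-sided because the analyses this mirrors were run in R,
whose default is two-sided, and the printed values are consistent with
that choice; sidedness is a flag. CN usage adjusts by BH (FDR < 20%),
mutation usage thresholds raw *p* (< 0.05). The mutation direction
imbalance feeds the majority count into the same binomial concordance
test. CN–expression integration uses Spearman (mid-rank ties) with BH
inside the tested gene set; a gene "passes" only with q < FDR, ρ > 0, and
higher mean expression in the high-risk group. An optional per-batch
median-centering is provided as a light batch-effect reduction before
cross-batch correlation; it is an approximation, not a ComBat equivalent.
PPI enrichment counts genes with ≥ 1 direct edge into the reference set
and compares query vs background fractions by two-sided Fisher.

## Synthetic data generator

All randomness flows through numpy's default PCG64 generator; each arm
draws from its own `SeedSequence([seed, tag])` stream, so outputs are
bit-identical across runs and platforms for a fixed seed. The generator's
defaults mirror the study's cohort shapes: 28 cell lines (17 resistant /
11 sensitive), a 35-patient treated discovery cohort, the two planted
signature pairs with hazard ratio 2.78, and a two-group multi-omics cohort
with seven planted gain regions named after the reported cytobands.

Quantities the study never states are one-time calibration choices:

- expression noise is Normal with σ = 1 on the log2 scale, gene means
  uniform on [4, 10]; planted DEGs shift by 1.5 log2 units with
  alternating sign;
- GI₅₀ is log-normal (subtype means 1.5 log10 apart, spread 0.25);
  GI₅₀-coupled genes are built as r·z(GI₅₀) + √(1−r²)·noise with target
  Pearson r = 0.8 on the stored (exponentiated) scale;
- survival is exponential with a multiplicative hazard on the unanimous
  high-risk vote (the simplest model satisfying proportional hazards);
  censoring is independent uniform administrative censoring on [0, h],
  with h solved by root-finding so the expected censoring probability
  matches the requested rate (capped at the follow-up horizon);
- per-pair REO votes are drawn through a latent risk label: high-risk
  samples vote high on every pair; low-risk samples vote all-low with
  probability 0.7, otherwise a mixed non-unanimous pattern. Real pair
  orderings are strongly correlated; fully independent votes would make
  the vote groups degenerate and the pair genes non-monotone in risk;
- each pair's first gene shifts down by 1.5 log2 units in high-risk
  samples, so individual genes (not only orderings) carry survival
  signal, as the funnel's OS stage requires;
- methylation is logit-normal (μ = −1, σ = 0.8) with a +1.5 logit shift
  in the high-risk group for planted genes, and expression couples
  negatively with configurable strength; copy-number dosage adds
  0.8 log2 per copy to expression.

What the generator does **not** emulate: probe-level structure, platform
mapping noise, copy-number segment geometry, mutation signatures,
non-proportional hazards, and informative censoring. Passing tests
therefore certify the statistical machinery and its null behavior, not
performance on real cohorts.

At the study's discovery size (n = 35, ~24 events) the funnel's power is
intrinsically limited — the study itself retained 2 of 36 candidate pairs —
so the end-to-end recovery demonstrations run at n = 200 patients (the
same scale as the power analyses), while n = 35 remains the default
condition.

## Numerical choices

- REO ties (*Eₐ* = *E_b*) fall in the *not-(a<b)* group and never vote
  high risk; ties are vanishingly rare on continuous data.
- Fisher tests delegate to scipy; the suite proves equality with exact
  integer hypergeometric enumeration over every 2×2 table with N ≤ 60.
- BH q-values delegate to statsmodels and are checked against a
  brute-force step-up implementation; degenerate tests carry NaN and do
  not count toward the family size.
- The binomial tail is `binom.sf(s−1, k, Pe)` with the s = 0 case pinned
  to 1 exactly.
- Manifest floats are rounded to 10 decimals before JSON so reruns are
  byte-identical.

## Problem sizes used by the test suite

Power and recovery checks run at the sizes stated above (200 replicates of
n = 200 for pair-scan power; 50 replicates of n = 500 for Cox coverage;
30-50 seeds for null-rate checks on reduced matrices). These are the
package's chosen verification sizes; larger replications only sharpen the
same estimates.

## Known limitations

- The Breslow solver is a cross-check tool; Efron/lifelines is the
  supported inference path.
- `rank_products`' exact-null mode is for small problems (the product
  distribution DP grows with Gᵏ distinct values) and guards itself with an
  error.
- The hypergeometric enrichment universe defaults to the analyzed matrix's
  genes after filtering; results always report the universe size used, and
  the choice of universe materially affects p-values.
- Pearson correlation on the stored GI₅₀ scale (not log) follows the
  source analyses; users with strongly skewed response values may prefer
  to log-transform upstream.
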