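"""Concordance scores and their cumulative-binomial significance test.

Given two analyses that each assign a direction (sign) to genes, the
concordance score over the k genes common to both is s/k, where s is the
number of genes whose directions agree. Under the null each gene agrees
independently with probability Pe (0.5 throughout), so the chance of
observing s or more agreements is the upper binomial tail

    P = P(X >= s) = 1 - sum_{i=0}^{s-1} C(k,i) Pe^i (1-Pe)^(k-i),
    X ~ Binomial(k, Pe),

computed through the regularized incomplete beta function so it stays
accurate for k up to 1e5 and tails far below double rounding of the naive
sum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as st

__all__ = ["ConcordanceResult", "concordance_binomial", "sign_concordance"]

MODES = ("deg_direction", "gi50_vs_os", "methylation_vs_expression")


@dataclass(frozen=True)
class ConcordanceResult:
    """k comparable items, s concordant, score = s/k, upper binomial tail p."""

    k: int
    s: int
    score: float
    p_value: float
    pe: float = 0.5

    def __post_init__(self) -> None:
        assert 0 <= self.s <= self.k
        assert 0.0 <= self.score <= 1.0
        assert 0.0 <= self.p_value <= 1.0


def concordance_binomial(k: int, s: int, pe: float = 0.5) -> ConcordanceResult:
    """Concordance score s/k with its cumulative-binomial tail probability.

    ``pe`` is the per-item null concordance probability. P(X >= 0) = 1 by
    convention (the lower sum is empty).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if not 0 <= s <= k:
        raise ValueError(f"s must lie in [0, k]; got s={s}, k={k}")
    if not 0.0 < pe < 1.0:
        raise ValueError("Pe must lie in (0, 1)")
    # survival function at s-1 == upper tail P(X >= s); scipy evaluates it
    # via the regularized incomplete beta, stable for large k
    p = float(st.binom.sf(s - 1, k, pe)) if s > 0 else 1.0
    return ConcordanceResult(k=int(k), s=int(s), score=s / k, p_value=min(p, 1.0),
                             pe=pe)


def _directions(table: pd.DataFrame) -> pd.Series:
    if "statistic" not in table.columns:
        raise ValueError("gene statistic table must have a 'statistic' column")
    return np.sign(table["statistic"].astype(float))


def sign_concordance(table_a: pd.DataFrame, table_b: pd.DataFrame,
                     mode: str = "deg_direction", pe: float = 0.5) -> ConcordanceResult:
    """Direction concordance between two per-gene statistic tables.

    Tables are indexed by gene with a signed ``statistic`` column (t, Pearson
    r, Cox log-hazard beta, or a methylation effect). Modes:

    - ``deg_direction``: concordant when the effect signs agree (same
      up/down deregulation in both analyses).
    - ``gi50_vs_os``: table_a holds Pearson r against GI50, table_b Cox
      log-hazard beta; a gene whose expression tracks drug resistance
      (r > 0) should carry higher hazard (beta > 0), so concordant when
      sign(r) == sign(beta).
    - ``methylation_vs_expression``: table_a holds the methylation effect
      (positive = hypermethylated), table_b the expression effect;
      concordant when the signs are opposite (hypermethylation with
      down-regulation, hypomethylation with up-regulation).
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}, got {mode!r}")
    common = table_a.index.intersection(table_b.index)
    if len(common) == 0:
        raise ValueError("gene intersection of the two tables is empty (k = 0)")
    sa = _directions(table_a.loc[common])
    sb = _directions(table_b.loc[common])
    if mode == "methylation_vs_expression":
        concordant = (sa == -sb) & (sa != 0)
    else:
        concordant = (sa == sb) & (sa != 0)
    return concordance_binomial(k=len(common), s=int(concordant.sum()), pe=pe)
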