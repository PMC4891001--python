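"""Shared small statistics helpers: BH q-values and two-sided Fisher tests."""

from __future__ import annotations

import numpy as np
import scipy.stats as st
from statsmodels.stats.multitest import multipletests

__all__ = ["bh_qvalues", "fisher_two_sided"]


def bh_qvalues(p_values) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (q-values).

    NaN entries (degenerate tests) are passed through as NaN and do not
    count toward the family size.
    """
    p = np.asarray(p_values, dtype=float)
    q = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    if ok.any():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


def fisher_two_sided(table) -> tuple[float, float]:
    """Two-sided Fisher exact test on a 2x2 table.

    Returns (odds_ratio, p). The odds ratio is the sample (conditional MLE
    not needed here) cross-product ratio; inf when the denominator is zero.
    """
    a, b = table[0]
    c, d = table[1]
    if min(a, b, c, d) < 0:
        raise ValueError("table counts must be nonnegative")
    odds, p = st.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return float(odds), float(p)
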