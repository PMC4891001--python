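"""Independent oracle implementations used only by the test suite.

Each function re-derives a statistic from first principles (rational
arithmetic, exhaustive enumeration, direct risk-set summation, or its own
Newton iteration) without touching the library code paths it is used to
check.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

import numpy as np


def bh_bruteforce(p_values) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values by the direct step-up definition:
    q_(i) = min_{j >= i} min(1, m * p_(j) / j) on the sorted p-values."""
    p = np.asarray(p_values, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q_sorted = np.empty(m)
    running = 1.0
    for i in range(m - 1, -1, -1):
        running = min(running, m * p[order[i]] / (i + 1))
        q_sorted[i] = running
    out = np.empty(m)
    out[order] = q_sorted
    return out


def binom_tail_exact(k: int, s: int, pe: Fraction = Fraction(1, 2)) -> Fraction:
    """P(X >= s) for X ~ Binomial(k, pe) in exact rational arithmetic."""
    pe = Fraction(pe)
    return sum(Fraction(comb(k, i)) * pe ** i * (1 - pe) ** (k - i)
               for i in range(s, k + 1))


def hypergeom_pmf_exact(N: int, K: int, n: int, x: int) -> Fraction:
    """P(X = x) for X ~ Hypergeometric(N, K, n), exact."""
    return Fraction(comb(K, x) * comb(N - K, n - x), comb(N, n))


def hypergeom_tail_exact(N: int, K: int, n: int, x: int) -> Fraction:
    """P(X >= x), exact."""
    lo = max(0, n - (N - K))
    hi = min(K, n)
    return sum(hypergeom_pmf_exact(N, K, n, i) for i in range(max(x, lo), hi + 1))


def fisher_two_sided_enum(table) -> float:
    """Two-sided Fisher p by summing all hypergeometric outcomes whose
    probability does not exceed the observed one (the R convention)."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    return fisher_two_sided_enum_margins(r1, r2, c1)[a - max(0, c1 - r2)]


def fisher_two_sided_enum_margins(r1: int, r2: int, c1: int) -> list:
    """Two-sided Fisher p for every admissible top-left cell given fixed
    margins, via exact integer hypergeometric counts.

    The pmf numerators C(r1,x)*C(r2,c1-x) are exact integers, so the
    "probability not larger than observed" comparison is done in integer
    arithmetic (with a 1e-7 relative slack matching double-precision
    implementations) and only the final ratio is converted to float.
    """
    N = r1 + r2
    lo, hi = max(0, c1 - r2), min(r1, c1)
    xs = range(lo, hi + 1)
    counts = [comb(r1, x) * comb(r2, c1 - x) for x in xs]
    denom = comb(N, c1)
    order = sorted(range(len(counts)), key=counts.__getitem__)
    prefix = [0]
    for i in order:
        prefix.append(prefix[-1] + counts[i])
    sorted_counts = [counts[i] for i in order]
    out = [0.0] * len(counts)
    scale = 10 ** 7
    for i, n_obs in enumerate(counts):
        cutoff = n_obs * (scale + 1)
        # rightmost sorted index with count*scale <= cutoff
        j = _bisect_counts(sorted_counts, cutoff, scale)
        out[i] = prefix[j] / denom
    return out


def _bisect_counts(sorted_counts, cutoff, scale):
    lo, hi = 0, len(sorted_counts)
    while lo < hi:
        mid = (lo + hi) // 2
        if sorted_counts[mid] * scale <= cutoff:
            lo = mid + 1
        else:
            hi = mid
    return lo


def logrank_bruteforce(times, events, groups) -> float:
    """Two-group log-rank chi-square by direct risk-set summation."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    assert len(labels) == 2
    g1 = groups == labels[0]
    O1 = E1 = V = 0.0
    for t in np.unique(times[events == 1]):
        at_risk = times >= t
        n = at_risk.sum()
        n1 = (at_risk & g1).sum()
        d = ((times == t) & (events == 1)).sum()
        d1 = ((times == t) & (events == 1) & g1).sum()
        O1 += d1
        E1 += d * n1 / n
        if n > 1:
            V += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return (O1 - E1) ** 2 / V


def cox_univariate_newton(times, events, x, max_iter: int = 100,
                          tol: float = 1e-12) -> tuple[float, float]:
    """Univariate Cox partial-likelihood MLE with Efron tie handling, by a
    self-contained Newton iteration. Returns (beta_hat, se)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    x = np.asarray(x, dtype=float)
    beta = 0.0
    uniq = np.unique(times[events == 1])
    for _ in range(max_iter):
        U = 0.0
        I = 0.0
        w = np.exp(beta * x)
        for t in uniq:
            risk = times >= t
            tied = (times == t) & (events == 1)
            d = tied.sum()
            sw = w[risk].sum()
            swx = (w[risk] * x[risk]).sum()
            swx2 = (w[risk] * x[risk] ** 2).sum()
            tw = w[tied].sum()
            twx = (w[tied] * x[tied]).sum()
            twx2 = (w[tied] * x[tied] ** 2).sum()
            for l in range(d):
                f = l / d
                denom = sw - f * tw
                num1 = swx - f * twx
                num2 = swx2 - f * twx2
                U += x[tied].sum() / d - num1 / denom
                I += num2 / denom - (num1 / denom) ** 2
        step = U / I
        beta += step
        if abs(step) < tol:
            break
    return beta, 1.0 / np.sqrt(I)


def pearson_on_midranks(x, y) -> float:
    """Spearman rho as the Pearson correlation of mid-ranks, computed from
    the definition."""
    def midranks(v):
        v = np.asarray(v, dtype=float)
        order = np.argsort(v, kind="stable")
        ranks = np.empty(len(v))
        i = 0
        sv = v[order]
        while i < len(v):
            j = i
            while j + 1 < len(v) and sv[j + 1] == sv[i]:
                j += 1
            ranks[order[i:j + 1]] = (i + j) / 2 + 1
            i = j + 1
        return ranks
    rx, ry = midranks(x), midranks(y)
    rx -= rx.mean()
    ry -= ry.mean()
    return float((rx * ry).sum() / np.sqrt((rx ** 2).sum() * (ry ** 2).sum()))


def rank_product_null_bruteforce(n_genes: int, k: int, observed_products):
    """Expected null count of features with rank product <= each observed
    value, by enumerating all n_genes**k equally likely rank combinations of
    one feature (its marginal null under within-comparison permutation),
    times n_genes."""
    grids = np.meshgrid(*[np.arange(1, n_genes + 1)] * k, indexing="ij")
    prods = np.ones(grids[0].shape, dtype=float)
    for g in grids:
        prods = prods * g
    prods = prods.ravel()
    out = []
    for obs in observed_products:
        out.append(n_genes * np.mean(prods <= obs * (1 + 1e-9)))
    return np.asarray(out)
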