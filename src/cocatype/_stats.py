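"""Shared exact-test helpers.

Two-by-two association testing appears in every driver cascade of the
pipeline (mutation enrichment, SCNA enrichment, methylation dichotomization,
checkpoint-category enrichment).  The two-sided Fisher exact test used here
sums, over the hypergeometric support fixed by the table margins, every
point probability not exceeding that of the observed table; a relative
slack of 1e-12 absorbs floating-point noise on exact probability ties
(distinct hypergeometric point masses on small tables differ by far more
than that).
"""

from __future__ import annotations

import numpy as np
from scipy import stats


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact P for the table [[a, b], [c, d]].

    Rows are condition (e.g. in-subtype / rest), columns are status
    (e.g. altered / unaltered).  Returns the two-sided P-value obtained by
    summing all tables, with the observed margins, whose point probability
    is <= that of the observed table (up to a 1e-12 relative tie slack).
    """
    for v in (a, b, c, d):
        if v < 0 or int(v) != v:
            raise ValueError("table entries must be nonnegative integers")
    a, b, c, d = int(a), int(b), int(c), int(d)
    n = a + b + c + d
    if n == 0:
        return 1.0
    row1 = a + b
    col1 = a + c
    lo = max(0, row1 + col1 - n)
    hi = min(row1, col1)
    support = np.arange(lo, hi + 1)
    pmf = stats.hypergeom.pmf(support, n, col1, row1)
    p_obs = pmf[a - lo]
    p = float(pmf[pmf <= p_obs * (1.0 + 1e-12)].sum())
    return min(p, 1.0)


def chi2_or_fisher_2x2(table: np.ndarray) -> tuple[float, float, str]:
    """Pearson chi-square on a 2x2 table, falling back to Fisher when any
    expected cell count is below 5 or a margin is zero.

    Returns ``(statistic, p, method)`` where method is ``"chi2"`` or
    ``"fisher"`` (statistic is NaN for the Fisher branch).  No continuity
    correction is applied on the chi-square branch.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    rows = t.sum(axis=1)
    cols = t.sum(axis=0)
    n = t.sum()
    if n == 0 or np.any(rows == 0) or np.any(cols == 0):
        p = fisher_exact_2x2(*t.astype(int).ravel())
        return float("nan"), p, "fisher"
    expected = np.outer(rows, cols) / n
    if np.any(expected < 5):
        p = fisher_exact_2x2(*t.astype(int).ravel())
        return float("nan"), p, "fisher"
    stat, p, _, _ = stats.chi2_contingency(t, correction=False)
    return float(stat), float(p), "chi2"
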