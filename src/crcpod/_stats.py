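"""Shared low-level statistical helpers."""

from __future__ import annotations

import numpy as np
from scipy import stats

#: Group sizes at or below this use the exact rank-sum null when no ties.
EXACT_RANKSUM_MAX_N = 10


def rank_sum_test(a, b) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    Exact enumeration when min(n) <= 10 and the pooled sample is tie-free;
    otherwise the normal approximation with tie correction and no
    continuity correction.  Degenerate input (all values identical in both
    groups) returns p = 1 by convention.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return 1.0
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (min(a.size, b.size) <= EXACT_RANKSUM_MAX_N and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method, use_continuity=False)
    return float(min(res.pvalue, 1.0))


def pooled_t_test(a, b, welch: bool = False) -> float:
    """Two-sided Student's t p-value, pooled variance by default.

    Zero variance in both groups yields p = 1 for equal means (no evidence
    against the null) and p = 0 otherwise (infinitely separated groups).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    if np.var(a) == 0.0 and np.var(b) == 0.0:
        return 1.0 if a.mean() == b.mean() else 0.0
    res = stats.ttest_ind(a, b, equal_var=not welch)
    return float(res.pvalue)
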