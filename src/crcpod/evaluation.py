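"""Model evaluation and demographic-table statistics.

ROC/AUC quantifies how well POD scores separate cases from controls; the
AUC equals the Mann-Whitney probability P(case score > control score) with
ties counted half.  The remaining functions are the tests used on
participant characteristics tables: Fisher's exact test for 2x2 categorical
splits, Student's t for quantitative variables, the Pearson chi-square for
r x c tables, one-way ANOVA for more than two groups, and simple percentage
summaries for follow-up counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score, roc_curve

from ._stats import pooled_t_test, rank_sum_test

#: Relative slack when comparing hypergeometric point probabilities in the
#: two-sided Fisher rule, matching the convention of the standard R and
#: SciPy implementations so equally-probable tables are always included.
_FISHER_RELATIVE_SLACK = Fraction(10_000_001, 10_000_000)


@dataclass
class ROCResult:
    """ROC curve plus its area."""

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


@dataclass
class ContingencyTable:
    """Nonnegative integer r x c cross-tabulation."""

    values: np.ndarray
    row_labels: list[str] | None = None
    col_labels: list[str] | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.ndim != 2:
            raise ValueError("contingency table must be 2-D")
        if not np.issubdtype(v.dtype, np.integer):
            if not np.allclose(v, np.round(v)):
                raise ValueError("contingency table must hold integers")
            v = np.round(v).astype(np.int64)
        if (v < 0).any():
            raise ValueError("negative counts")
        self.values = v.astype(np.int64)


def roc_auc(scores, labels) -> ROCResult:
    """ROC curve and AUC for case/control scores.

    ``labels`` is a boolean case indicator.  The AUC from the trapezoidal
    curve equals the pairwise probability estimate
    P(score_case > score_control) + 0.5 * P(tie) exactly.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if scores.size != y.size:
        raise ValueError("scores and labels differ in length")
    if y.all() or not y.any():
        raise ValueError("both classes must be present")
    fpr, tpr, thr = roc_curve(y, scores)
    return ROCResult(thr, fpr, tpr, float(roc_auc_score(y, scores)))


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p-value by the point-probability rule.

    Sums the hypergeometric probabilities (margins fixed) of every table
    whose point probability does not exceed the observed one, using exact
    rational arithmetic so the sum is immune to floating-point ordering.
    A zero margin leaves a single admissible table: p = 1 by convention.
    """
    t = ContingencyTable(np.asarray(table)) if not isinstance(table, ContingencyTable) else table
    if t.values.shape != (2, 2):
        raise ValueError("fisher_exact_2x2 needs a 2x2 table")
    a, b = int(t.values[0, 0]), int(t.values[0, 1])
    c, d = int(t.values[1, 0]), int(t.values[1, 1])
    n = a + b + c + d
    r1, c1 = a + b, a + c
    if r1 == 0 or c1 == 0 or r1 == n or c1 == n:
        return 1.0
    denom = comb(n, c1)
    k_min, k_max = max(0, c1 - (n - r1)), min(r1, c1)
    probs = {
        k: Fraction(comb(r1, k) * comb(n - r1, c1 - k), denom)
        for k in range(k_min, k_max + 1)
    }
    cutoff = probs[a] * _FISHER_RELATIVE_SLACK
    p = sum(pk for pk in probs.values() if pk <= cutoff)
    return float(min(p, Fraction(1)))


def t_test(a, b, welch: bool = False) -> float:
    """Two-sided Student's t (pooled variance; ``welch`` for unequal)."""
    return pooled_t_test(a, b, welch=welch)


def t_test_from_stats(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int, welch: bool = False
) -> float:
    """Two-sided t from printed summary statistics (mean, SD, n per group)."""
    res = stats.ttest_ind_from_stats(mean1, sd1, n1, mean2, sd2, n2, equal_var=not welch)
    return float(res.pvalue)


def chi_square_rxc(table) -> float:
    """Pearson chi-square p-value for an r x c table, no continuity
    correction.  A zero expected cell makes the statistic undefined; the
    error suggests Fisher's exact test instead."""
    t = ContingencyTable(np.asarray(table)) if not isinstance(table, ContingencyTable) else table
    v = t.values
    if v.shape[0] < 2 or v.shape[1] < 2:
        raise ValueError("need at least a 2x2 table")
    expected = np.outer(v.sum(axis=1), v.sum(axis=0)) / v.sum()
    if (expected == 0).any():
        raise ValueError("zero expected cell; use fisher_exact_2x2 (or collapse categories)")
    res = stats.chi2_contingency(v, correction=False)
    return float(res.pvalue)


def anova_oneway(groups) -> float:
    """One-way ANOVA p-value across two or more groups.

    Zero within-group variance with equal means returns p = 1; with
    unequal means, p = 0 (groups infinitely separated).
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2 or any(g.size < 2 for g in arrays):
        raise ValueError("need >= 2 groups with >= 2 observations each")
    pooled = np.concatenate(arrays)
    if all(np.var(g) == 0.0 for g in arrays):
        means = [g.mean() for g in arrays]
        return 1.0 if np.all(np.asarray(means) == means[0]) else 0.0
    res = stats.f_oneway(*arrays)
    return float(res.pvalue)


def proportion(numerator: int, denominator: int) -> float:
    """Percentage 100*num/den rounded to 2 decimals (follow-up summaries)."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    if numerator < 0 or numerator > denominator:
        raise ValueError("numerator must lie in [0, denominator]")
    return round(100.0 * numerator / denominator, 2)


def compare_pod(scores_by_group: dict) -> pd.DataFrame:
    """Pairwise two-sided rank-sum p-values between group POD score sets,
    one row per unordered group pair, no multiplicity adjustment."""
    labels = sorted(scores_by_group)
    records = []
    for ga, gb in combinations(labels, 2):
        records.append(
            {
                "group_a": ga,
                "group_b": gb,
                "p_value": rank_sum_test(scores_by_group[ga], scores_by_group[gb]),
            }
        )
    return pd.DataFrame.from_records(records)


def format_p(p: float) -> str:
    """Display convention: 3 decimals, floored at "<0.001"."""
    return "<0.001" if p < 0.001 else f"{p:.3f}"
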