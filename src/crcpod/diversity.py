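"""Within-sample (alpha) diversity indices and group comparison.

Four indices are computed per sample: Shannon entropy (nats), the Simpson
complement 1 - Σp², the observed taxon count, and the Gini inequality
coefficient of the abundance vector.  Shannon and Simpson grow with
diversity; Gini grows with unevenness.  Gini is computed over the full
taxon vector of the table, structural zeros included, so values are
comparable across samples of one aligned table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._stats import pooled_t_test, rank_sum_test
from .io_tables import AbundanceTable, SampleMetadata
from .preprocess import to_proportions


@dataclass(frozen=True)
class DiversityResult:
    sample_id: str
    shannon: float      # nats, >= 0
    simpson: float      # 1 - sum p^2, in [0, 1)
    observed: int       # taxa with abundance > 0
    gini: float         # inequality of the full abundance vector, [0, 1)


def diversity_indices(profile, sample_id: str = "") -> DiversityResult:
    """Alpha diversity of one nonnegative abundance vector.

    The vector is re-closed to sum 1 internally, so any uniform rescaling
    of the input (percent vs proportion) gives identical results.
    """
    p = np.asarray(profile, dtype=float)
    if (p < 0).any():
        raise ValueError("negative abundances")
    total = p.sum()
    if total <= 0:
        raise ValueError(f"all-zero profile{' for ' + sample_id if sample_id else ''}")
    p = p / total
    pos = p[p > 0]
    shannon = float(-(pos * np.log(pos)).sum())
    simpson = float(1.0 - (p**2).sum())
    observed = int((p > 0).sum())
    gini = _gini(p)
    return DiversityResult(sample_id, shannon, simpson, observed, gini)


def _gini(p: np.ndarray) -> float:
    """Gini coefficient via the sorted-rank identity; zeros included."""
    n = p.size
    if n == 1:
        return 0.0
    s = np.sort(p)
    cum = np.cumsum(s)
    # G = (n + 1 - 2 * sum(cum) / cum[-1]) / n
    return float((n + 1 - 2.0 * cum.sum() / cum[-1]) / n)


def alpha_diversity(table: AbundanceTable) -> pd.DataFrame:
    """Per-sample index table (rows = samples) for a whole abundance table."""
    table = to_proportions(table)
    rows = [diversity_indices(table.data[s].to_numpy(), s) for s in table.sample_ids]
    return pd.DataFrame(
        {
            "shannon": [r.shannon for r in rows],
            "simpson": [r.simpson for r in rows],
            "observed": [r.observed for r in rows],
            "gini": [r.gini for r in rows],
        },
        index=pd.Index(table.sample_ids, name="sample_id"),
    )


def compare_diversity(values_a, values_b, test: str = "t") -> float:
    """Two-sided p-value comparing one diversity index between two groups.

    ``test`` is ``"t"`` (Student's pooled t) or ``"wilcoxon"`` (rank-sum).
    Both are offered because parametric and rank-based comparisons of alpha
    diversity are each common; they can disagree on small skewed samples.
    """
    if test == "t":
        return pooled_t_test(values_a, values_b)
    if test == "wilcoxon":
        return rank_sum_test(values_a, values_b)
    raise ValueError(f"unknown test {test!r}; use 't' or 'wilcoxon'")


def compare_groups(
    diversity_frame: pd.DataFrame,
    metadata: SampleMetadata,
    test: str = "t",
) -> pd.DataFrame:
    """All pairwise group comparisons for every index column."""
    groups = metadata.groups.loc[diversity_frame.index]
    labels = sorted(groups.unique())
    records = []
    for i, ga in enumerate(labels):
        for gb in labels[i + 1:]:
            for col in diversity_frame.columns:
                a = diversity_frame.loc[groups == ga, col].to_numpy()
                b = diversity_frame.loc[groups == gb, col].to_numpy()
                records.append(
                    {"index": col, "group_a": ga, "group_b": gb,
                     "p_value": compare_diversity(a, b, test=test)}
                )
    return pd.DataFrame.from_records(records)
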