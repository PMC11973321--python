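"""Per-cohort differential-abundance screening and cross-cohort biomarker
selection.

Each taxon is screened with a two-tailed Wilcoxon rank-sum test between
case and control samples at an unadjusted threshold (alpha = 0.05 by
default, mirroring common practice in cross-cohort marker discovery where
the real multiplicity control comes from requiring agreement across
independent cohorts rather than from a per-cohort FDR step).  Candidate
biomarkers are the taxa significant in any screening cohort that are also
detected in the target cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import rank_sum_test
from .io_tables import AbundanceTable, SampleMetadata
from .preprocess import to_proportions

DEFAULT_ALPHA = 0.05


class EmptyPanelError(ValueError):
    """No taxon survived the overlap; model training cannot proceed."""


@dataclass
class BiomarkerPanel:
    """Taxa surviving the cross-cohort screen.

    ``source_cohorts`` records which screening cohorts flagged each taxon;
    ``importance`` is filled in later by the POD model (mean decrease
    accuracy) and is None until then.
    """

    taxon_ids: list[str]
    source_cohorts: dict[str, list[str]] = field(default_factory=dict)
    importance: dict[str, float] | None = None

    def __post_init__(self) -> None:
        if len(set(self.taxon_ids)) != len(self.taxon_ids):
            raise ValueError("duplicate taxa in panel")

    def __len__(self) -> int:
        return len(self.taxon_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "taxon_id": self.taxon_ids,
                "source_cohorts": [
                    ";".join(self.source_cohorts.get(t, [])) for t in self.taxon_ids
                ],
                "importance": [
                    (self.importance or {}).get(t, np.nan) for t in self.taxon_ids
                ],
            }
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "BiomarkerPanel":
        taxa = frame["taxon_id"].astype(str).tolist()
        sources = {
            t: [c for c in str(s).split(";") if c and c != "nan"]
            for t, s in zip(taxa, frame.get("source_cohorts", [""] * len(taxa)))
        }
        imp = None
        if "importance" in frame and frame["importance"].notna().any():
            imp = dict(zip(taxa, frame["importance"].astype(float)))
        return cls(taxa, sources, imp)


def case_control_labels(
    metadata: SampleMetadata,
    case_group: str = "CRC",
    control_group: str = "Control",
) -> pd.Series:
    """Boolean case indicator restricted to the two groups of interest."""
    groups = metadata.groups
    keep = groups.isin([case_group, control_group])
    if (groups[keep] == case_group).sum() == 0 or (groups[keep] == control_group).sum() == 0:
        raise ValueError(
            f"need samples in both {case_group!r} and {control_group!r}"
        )
    return (groups[keep] == case_group)


def wilcoxon_screen(
    table: AbundanceTable,
    labels: pd.Series | np.ndarray,
    alpha: float = DEFAULT_ALPHA,
    cohort: str = "",
) -> pd.DataFrame:
    """Two-tailed rank-sum test per taxon, no multiplicity adjustment.

    ``labels`` is a boolean case indicator over (a subset of) the table's
    samples.  Returns one row per taxon with the p-value, the direction
    sign(median_case - median_control), and the significance flag.
    """
    table = to_proportions(table)
    if isinstance(labels, pd.Series):
        table = table.subset_samples(list(labels.index))
        y = labels.to_numpy(dtype=bool)
    else:
        y = np.asarray(labels, dtype=bool)
        if y.size != table.n_samples:
            raise ValueError("labels length does not match sample count")
    if y.sum() < 2 or (~y).sum() < 2:
        raise ValueError("each group needs at least 2 samples")
    X = table.values  # taxa × samples
    case, ctrl = X[:, y], X[:, ~y]
    records = []
    for i, taxon in enumerate(table.taxon_ids):
        p = rank_sum_test(case[i], ctrl[i])
        direction = int(np.sign(np.median(case[i]) - np.median(ctrl[i])))
        records.append(
            {
                "cohort": cohort,
                "taxon_id": taxon,
                "p_value": p,
                "direction": direction,
                "significant": bool(p < alpha),
            }
        )
    return pd.DataFrame.from_records(records)


def detected_taxa(tables: Iterable[AbundanceTable]) -> set[str]:
    """Taxa with nonzero abundance in at least one sample of any table."""
    out: set[str] = set()
    for t in tables:
        nonzero = t.data.index[(t.data > 0).any(axis=1)]
        out.update(nonzero)
    return out


def overlap_biomarkers(
    screens: Sequence[pd.DataFrame],
    detected: set[str],
    mode: str = "union",
) -> BiomarkerPanel:
    """Combine per-cohort screens into a biomarker panel.

    ``mode="union"`` takes taxa significant in any screening cohort (the
    default: per-cohort marker sets are expected to be nested within the
    combined panel); ``mode="intersection"`` demands significance in every
    cohort.  Either way the result is intersected with the taxa actually
    detected in the target cohorts, since a marker absent from the target
    data carries no information there.
    """
    if not screens:
        raise ValueError("need at least one screen")
    if mode not in ("union", "intersection"):
        raise ValueError(f"unknown overlap mode {mode!r}")
    sig_sets = []
    sources: dict[str, list[str]] = {}
    for screen in screens:
        sig = screen.loc[screen["significant"], ["taxon_id", "cohort"]]
        sig_sets.append(set(sig["taxon_id"]))
        for t, c in zip(sig["taxon_id"], sig["cohort"]):
            sources.setdefault(t, []).append(str(c))
    combined = set.union(*sig_sets) if mode == "union" else set.intersection(*sig_sets)
    panel_taxa = sorted(combined & detected)
    if not panel_taxa:
        raise EmptyPanelError(
            "no significant taxon is detected in the target cohorts; "
            "training cannot proceed (relax alpha or check alignment)"
        )
    return BiomarkerPanel(panel_taxa, {t: sources[t] for t in panel_taxa})


def covariate_correlation(
    table: AbundanceTable,
    covariate,
    alpha: float = DEFAULT_ALPHA,
) -> pd.DataFrame:
    """Spearman correlation of every taxon with a per-sample covariate.

    Spearman is used because relative abundances are compositional and
    zero-inflated; a rank correlation is robust to both.  The covariate may
    be binary (e.g. a dietary indicator) or numeric.
    """
    table = to_proportions(table)
    cov = np.asarray(covariate, dtype=float)
    if cov.size != table.n_samples:
        raise ValueError("covariate length does not match sample count")
    if np.all(cov == cov[0]):
        raise ValueError("constant covariate: correlation undefined")
    X = table.values
    records = []
    for i, taxon in enumerate(table.taxon_ids):
        if np.all(X[i] == X[i, 0]):
            rho, p = 0.0, 1.0
        else:
            rho, p = stats.spearmanr(X[i], cov)
        records.append(
            {"taxon_id": taxon, "rho": float(rho), "p_value": float(p),
             "significant": bool(p < alpha)}
        )
    return pd.DataFrame.from_records(records)
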