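"""Abundance-table and metadata containers plus TSV I/O.

The pipeline's universal currency is the :class:`AbundanceTable`: a taxa ×
samples matrix of relative abundances as produced by marker-gene profilers
(MetaPhlAn-style merged tables, percent scale, one column per sample).
Metadata carries per-sample cohort, group label and covariates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

#: Closed set of group labels used throughout the pipeline.
VALID_GROUPS = frozenset({"CRC", "Control", "Relative", "Staff"})

#: Acceptable deviation of a per-sample percent column sum from 100 in
#: strict mode.  Profilers leave unclassified mass, so some slack is normal.
DEFAULT_SUM_TOLERANCE = 1.0


class TableFormatError(ValueError):
    """Malformed table on disk: duplicates, non-numeric cells, bad header."""


class TableValidationError(ValueError):
    """Well-formed table violating a numeric invariant (negative values,
    out-of-tolerance column sums, mismatched sample sets)."""


def infer_rank(taxon_ids: Sequence[str]) -> str:
    """Infer the taxonomic rank from the deepest lineage prefix present.

    MetaPhlAn lineage strings are pipe-delimited with one-letter rank
    prefixes (``k__|p__|...|g__|s__``).  Plain species names (no prefix)
    default to ``species``.
    """
    deepest = "species"
    for tid in taxon_ids:
        leaf = tid.rsplit("|", 1)[-1]
        if leaf.startswith("s__"):
            return "species"
        if leaf.startswith("g__"):
            deepest = "genus"
    return deepest


@dataclass
class AbundanceTable:
    """Taxa × samples relative-abundance matrix.

    Parameters
    ----------
    data:
        DataFrame with taxon ids as the index and sample ids as columns.
        Values are relative abundances; ``scale`` records the unit.
    rank:
        Taxonomic rank tag, ``"species"`` or ``"genus"``.
    scale:
        ``"percent"`` (profiler convention, columns sum to ~100),
        ``"proportion"`` (columns sum to ~1) or ``"log10"`` (after the
        pseudo-count log transform; no longer compositional).
    """

    data: pd.DataFrame
    rank: str = "species"
    scale: str = "percent"

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dup = self.data.index[self.data.index.duplicated()].tolist()
            raise TableFormatError(f"duplicate taxon ids: {dup[:5]}")
        if self.data.columns.has_duplicates:
            dup = self.data.columns[self.data.columns.duplicated()].tolist()
            raise TableFormatError(f"duplicate sample ids: {dup[:5]}")
        values = self.data.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise TableFormatError("non-numeric cells in abundance table")
        if np.isnan(values).any():
            raise TableValidationError("missing cells; absent taxa must be explicit zeros")
        if self.scale != "log10" and (values < 0).any():
            raise TableValidationError("negative abundance values")
        self.data = self.data.astype(float)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def values(self) -> np.ndarray:
        """Matrix view, taxa rows × sample columns."""
        return self.data.to_numpy()

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def n_taxa(self) -> int:
        return self.data.shape[0]

    def sample_matrix(self) -> np.ndarray:
        """Samples × taxa matrix (the orientation models consume)."""
        return self.data.to_numpy().T

    def validate_percent_sums(self, tolerance: float = DEFAULT_SUM_TOLERANCE) -> None:
        """Strict percent-scale check: every column sum within ``tolerance``
        of 100.  Not applied by default because many real tables carry
        unclassified mass or sub-rank subsets."""
        if self.scale != "percent":
            raise TableValidationError(f"table is on the {self.scale} scale, not percent")
        sums = self.data.sum(axis=0)
        bad = sums[(sums - 100.0).abs() > tolerance]
        if not bad.empty:
            raise TableValidationError(
                f"column sums outside 100±{tolerance}: "
                + ", ".join(f"{s}={v:.3f}" for s, v in bad.items())
            )

    def subset_samples(self, sample_ids: Sequence[str]) -> "AbundanceTable":
        missing = [s for s in sample_ids if s not in self.data.columns]
        if missing:
            raise TableValidationError(f"unknown sample ids: {missing[:5]}")
        return replace(self, data=self.data.loc[:, list(sample_ids)].copy())

    def copy(self) -> "AbundanceTable":
        return replace(self, data=self.data.copy())


@dataclass
class SampleMetadata:
    """Per-sample cohort, group label and covariates.

    ``frame`` is indexed by sample id with at least the columns ``cohort``
    and ``group``; any further columns are covariates (binary or numeric).
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        for col in ("cohort", "group"):
            if col not in self.frame.columns:
                raise TableFormatError(f"metadata missing mandatory column {col!r}")
        if self.frame.index.has_duplicates:
            raise TableFormatError("duplicate sample ids in metadata")
        bad = set(self.frame["group"]) - VALID_GROUPS
        if bad:
            raise TableValidationError(
                f"unknown group labels {sorted(bad)}; expected one of {sorted(VALID_GROUPS)}"
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame.index)

    @property
    def groups(self) -> pd.Series:
        return self.frame["group"]

    @property
    def cohorts(self) -> pd.Series:
        return self.frame["cohort"]

    def covariate(self, name: str) -> pd.Series:
        if name not in self.frame.columns or name in ("cohort", "group"):
            raise KeyError(f"no covariate {name!r}")
        return self.frame[name]

    def matched_to(self, table: AbundanceTable) -> "SampleMetadata":
        """Validate the 1:1 pairing with ``table`` and return metadata in
        table column order."""
        meta_ids = set(self.frame.index)
        table_ids = set(table.sample_ids)
        if meta_ids != table_ids:
            raise TableValidationError(
                f"metadata/table sample mismatch: {sorted(meta_ids ^ table_ids)[:5]}"
            )
        return SampleMetadata(self.frame.loc[table.sample_ids].copy())


@dataclass
class CohortCollection:
    """Cohort-keyed set of (AbundanceTable, SampleMetadata) pairs sharing a
    taxon namespace after :func:`align_cohorts`."""

    cohorts: dict[str, tuple[AbundanceTable, SampleMetadata]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for label, (table, meta) in self.cohorts.items():
            meta.matched_to(table)

    @property
    def labels(self) -> list[str]:
        return list(self.cohorts)

    def table(self, label: str) -> AbundanceTable:
        return self.cohorts[label][0]

    def metadata(self, label: str) -> SampleMetadata:
        return self.cohorts[label][1]

    def aligned(self) -> "CohortCollection":
        tables = [t for t, _ in self.cohorts.values()]
        aligned = align_cohorts(tables)
        return CohortCollection(
            {
                label: (atab, meta)
                for (label, (_, meta)), atab in zip(self.cohorts.items(), aligned)
            }
        )


def read_abundance_table(
    path: str | Path,
    orientation: str = "rows-are-taxa",
    rank: str | None = None,
    strict_percent: bool = False,
    sum_tolerance: float = DEFAULT_SUM_TOLERANCE,
) -> AbundanceTable:
    """Read a tab-delimited abundance table.

    ``orientation`` selects whether rows hold taxa (profiler convention) or
    samples.  The taxonomic rank is inferred from lineage prefixes unless
    given.  With ``strict_percent`` every sample must sum to 100 within
    ``sum_tolerance``.
    """
    if orientation not in ("rows-are-taxa", "rows-are-samples"):
        raise ValueError(f"unknown orientation {orientation!r}")
    frame = pd.read_csv(path, sep="\t", index_col=0, header=0)
    try:
        frame = frame.apply(pd.to_numeric)
    except (ValueError, TypeError) as exc:
        raise TableFormatError(f"non-numeric cell in {path}: {exc}") from None
    if orientation == "rows-are-samples":
        frame = frame.T
    frame.index = frame.index.astype(str)
    frame.columns = frame.columns.astype(str)
    table = AbundanceTable(frame, rank=rank or infer_rank(frame.index))
    if strict_percent:
        table.validate_percent_sums(sum_tolerance)
    return table


def write_abundance_table(table: AbundanceTable, path: str | Path) -> None:
    out = table.data.copy()
    out.index.name = "taxon_id"
    out.to_csv(path, sep="\t", float_format="%.17g")


def read_metadata(path: str | Path) -> SampleMetadata:
    frame = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if "sample_id" not in frame.columns:
        raise TableFormatError("metadata must have a sample_id column")
    frame = frame.set_index("sample_id")
    return SampleMetadata(frame)


def write_metadata(meta: SampleMetadata, path: str | Path) -> None:
    out = meta.frame.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")


def align_cohorts(tables: Sequence[AbundanceTable]) -> list[AbundanceTable]:
    """Put every table on the union of taxa, in lexicographic order.

    Taxa absent from a cohort are filled with explicit zeros, so each
    sample's total abundance mass is conserved.  Mixing ranks is an error:
    a genus table and a species table do not share a namespace.
    """
    if not tables:
        raise ValueError("align_cohorts needs at least one table")
    ranks = {t.rank for t in tables}
    if len(ranks) > 1:
        raise TableValidationError(f"cannot align tables of mixed ranks {sorted(ranks)}")
    scales = {t.scale for t in tables}
    if len(scales) > 1:
        raise TableValidationError(f"cannot align tables of mixed scales {sorted(scales)}")
    union: set[str] = set()
    for t in tables:
        union.update(t.taxon_ids)
    order = sorted(union)
    return [
        replace(t, data=t.data.reindex(index=order, fill_value=0.0))
        for t in tables
    ]
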