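"""Normalization for microbiome feature comparison.

Profiler output is percent-scale; everything downstream works on
proportions.  For feature comparison the proportions additionally receive a
small pseudo-count followed by a log10 transform, which bounds the dynamic
range of near-zero abundances without changing any rank ordering —
rank-based tests are therefore unaffected, but parametric displays and
distance-free summaries behave better.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
from pydantic import BaseModel, ConfigDict, field_validator

from .io_tables import AbundanceTable, TableValidationError


class TransformParams(BaseModel):
    """Pseudo-count log-transform parameters.

    The default pseudo-count of 1e-05 is on the proportion scale, i.e. one
    part in 100,000 of a sample's classified mass, below the detection floor
    of typical shotgun profiles.
    """

    model_config = ConfigDict(extra="forbid")

    pseudocount: float = 1e-05
    log_base: float = 10.0

    @field_validator("pseudocount")
    @classmethod
    def _positive(cls, v: float) -> float:
        if v <= 0:
            raise ValueError("pseudocount must be > 0")
        return v


def to_proportions(table: AbundanceTable) -> AbundanceTable:
    """Percent → proportion scale (divide by 100, no re-closure).

    Idempotent: a table already tagged as proportion-scale passes through
    unchanged, so the conversion can sit safely at every pipeline entry.
    """
    if table.scale == "proportion":
        return table.copy()
    if table.scale != "percent":
        raise TableValidationError(f"cannot convert {table.scale}-scale table to proportions")
    return replace(table, data=table.data / 100.0, scale="proportion")


def log_transform(table: AbundanceTable, params: TransformParams | None = None) -> AbundanceTable:
    """v ↦ log_b(v + pseudocount) on a proportion-scale table.

    Strictly monotone, so order statistics (and hence Wilcoxon p-values)
    are preserved exactly.  A zero abundance maps to log10(1e-05) = -5 with
    the defaults.
    """
    params = params or TransformParams()
    if table.scale != "proportion":
        raise TableValidationError("log_transform expects a proportion-scale table; call to_proportions first")
    values = table.data.to_numpy()
    if (values < 0).any():
        raise TableValidationError("negative abundances cannot be log-transformed")
    out = np.log(values + params.pseudocount) / np.log(params.log_base)
    frame = table.data.copy()
    frame.loc[:, :] = out
    return replace(table, data=frame, scale="log10")
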