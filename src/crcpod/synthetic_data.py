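"""Multi-cohort case/control abundance simulation with planted signal.

The generator emulates the statistical structure the downstream analysis
assumes: per-taxon log-normal baseline abundances, a multiplicative
case/control shift on a planted subset of taxa, a per-(cohort, taxon)
multiplicative batch effect mimicking inter-study heterogeneity, closure to
relative abundances, and a binary diet covariate linked logistically to the
abundance of a designated taxon subset.  Every random draw descends from a
single seed through spawned substreams (one shared stream plus one per
cohort), so identical configurations reproduce bit-identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, model_validator

from .io_tables import AbundanceTable, CohortCollection, SampleMetadata

COVARIATE_NAME = "red_meat_gt150"


class SyntheticConfig(BaseModel):
    """One cohort's simulation parameters.

    ``effect_fold`` is the multiplicative abundance shift applied to planted
    taxa in cases; its magnitude is what matters (a fold of 0.25 behaves
    like 4 with the enriched/depleted roles swapped).  ``frac_depleted``
    controls how many planted taxa are shifted down rather than up, since
    disease-associated panels typically mix enriched pathobionts with
    depleted commensals.  ``batch_sd`` is the standard deviation of the
    per-(cohort, taxon) log-scale batch multiplier.
    """

    model_config = ConfigDict(extra="forbid")

    cohort: str = "cohort"
    n_taxa: int = 200
    n_case: int = 100
    n_control: int = 100
    n_diff: int = 20
    effect_fold: float = 4.0
    frac_depleted: float = 0.5
    base_logmean_sd: float = 1.0
    noise_sd: float = 1.0
    batch_sd: float = 0.5
    covariate_assoc: float = 0.0
    n_covariate_taxa: int = 10
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "SyntheticConfig":
        if self.n_taxa < 1:
            raise ValueError("n_taxa must be >= 1")
        if self.n_case < 1 or self.n_control < 1:
            raise ValueError("group sizes must be >= 1")
        if not 0 <= self.n_diff <= self.n_taxa:
            raise ValueError("n_diff must be in [0, n_taxa]")
        if self.effect_fold <= 0:
            raise ValueError("effect_fold must be > 0")
        if not 0.0 <= self.frac_depleted <= 1.0:
            raise ValueError("frac_depleted must be in [0, 1]")
        if not 0 <= self.n_covariate_taxa <= self.n_taxa:
            raise ValueError("n_covariate_taxa must be in [0, n_taxa]")
        return self


@dataclass(frozen=True)
class GroundTruth:
    """What was planted: taxon → effect sign (+1 enriched in cases,
    -1 depleted), plus the covariate-linked taxa."""

    planted_taxa: dict[str, int]
    covariate_taxa: list[str]

    @property
    def enriched(self) -> list[str]:
        return [t for t, s in self.planted_taxa.items() if s > 0]

    @property
    def depleted(self) -> list[str]:
        return [t for t, s in self.planted_taxa.items() if s < 0]


def _taxon_names(n: int) -> list[str]:
    return [f"s__Taxon_{i:04d}" for i in range(n)]


def _draw_planted(rng: np.random.Generator, cfg: SyntheticConfig) -> tuple[np.ndarray, np.ndarray]:
    idx = np.sort(rng.choice(cfg.n_taxa, size=cfg.n_diff, replace=False))
    n_dep = int(round(cfg.n_diff * cfg.frac_depleted))
    signs = np.ones(cfg.n_diff, dtype=int)
    if cfg.n_diff:
        dep = rng.choice(cfg.n_diff, size=n_dep, replace=False)
        signs[dep] = -1
    return idx, signs


def simulate_cohort(
    config: SyntheticConfig,
    rng: np.random.Generator | None = None,
    baseline: np.ndarray | None = None,
    planted: tuple[np.ndarray, np.ndarray] | None = None,
    covariate_idx: np.ndarray | None = None,
) -> tuple[AbundanceTable, SampleMetadata, GroundTruth]:
    """Simulate one case/control cohort.

    The optional ``rng`` / ``baseline`` / ``planted`` / ``covariate_idx``
    hooks let :func:`simulate_multi_cohort` share the taxon namespace,
    baseline and planted set across cohorts while keeping per-cohort noise
    streams independent.
    """
    cfg = config
    rng = rng or np.random.default_rng(np.random.SeedSequence(cfg.seed))
    taxa = _taxon_names(cfg.n_taxa)

    if baseline is None:
        baseline = rng.normal(0.0, cfg.base_logmean_sd, size=cfg.n_taxa)
    if planted is None:
        planted = _draw_planted(rng, cfg)
    if covariate_idx is None:
        covariate_idx = np.sort(rng.choice(cfg.n_taxa, size=cfg.n_covariate_taxa, replace=False))
    planted_idx, signs = planted

    n = cfg.n_case + cfg.n_control
    is_case = np.zeros(n, dtype=bool)
    is_case[: cfg.n_case] = True

    batch = rng.normal(0.0, cfg.batch_sd, size=cfg.n_taxa) if cfg.batch_sd > 0 else np.zeros(cfg.n_taxa)
    log_abund = (
        baseline[:, None]
        + batch[:, None]
        + rng.normal(0.0, cfg.noise_sd, size=(cfg.n_taxa, n))
    )
    # planted multiplicative shift in cases; |ln fold| so fold and 1/fold
    # describe the same magnitude of effect
    delta = abs(np.log(cfg.effect_fold))
    if cfg.n_diff and delta > 0:
        log_abund[np.ix_(planted_idx, is_case)] += (signs * delta)[:, None]

    abund = np.exp(log_abund)
    abund = abund / abund.sum(axis=0) * 100.0  # closure to percent scale

    sample_ids = [f"{cfg.cohort}_S{j:04d}" for j in range(n)]
    table = AbundanceTable(
        pd.DataFrame(abund, index=taxa, columns=sample_ids), rank="species", scale="percent"
    )

    # binary diet covariate: logistic link from the standardized total
    # proportion carried by the covariate taxa
    mass = abund[covariate_idx].sum(axis=0) / 100.0 if len(covariate_idx) else np.zeros(n)
    sd = mass.std()
    z = (mass - mass.mean()) / sd if sd > 0 else np.zeros(n)
    p_cov = 1.0 / (1.0 + np.exp(-cfg.covariate_assoc * z))
    covariate = (rng.random(n) < p_cov).astype(int)

    meta = SampleMetadata(
        pd.DataFrame(
            {
                "cohort": cfg.cohort,
                "group": np.where(is_case, "CRC", "Control"),
                COVARIATE_NAME: covariate,
            },
            index=pd.Index(sample_ids, name="sample_id"),
        )
    )
    truth = GroundTruth(
        planted_taxa={taxa[i]: int(s) for i, s in zip(planted_idx, signs)},
        covariate_taxa=[taxa[i] for i in covariate_idx],
    )
    return table, meta, truth


def simulate_multi_cohort(
    configs: list[SyntheticConfig],
    shared_planted: bool = True,
    seed: int | None = None,
) -> tuple[CohortCollection, dict[str, GroundTruth]]:
    """Simulate several cohorts on one taxon namespace.

    With ``shared_planted`` the same planted set (signs included) is used in
    every cohort, so the cross-cohort overlap of significant taxa is
    non-empty by construction; otherwise each cohort draws its own planted
    set and the overlap is at chance level.  The shared baseline log-means
    are drawn once; cohorts differ through their batch effects, noise and
    sample draws.  ``seed`` overrides the first config's seed as the master
    seed for all substreams.
    """
    if len(configs) < 2:
        raise ValueError("simulate_multi_cohort needs at least 2 configs")
    n_taxa = {c.n_taxa for c in configs}
    if len(n_taxa) > 1:
        raise ValueError("all cohorts must share n_taxa (one taxon namespace)")
    labels = [c.cohort for c in configs]
    if len(set(labels)) != len(labels):
        raise ValueError(f"duplicate cohort labels: {labels}")

    master = seed if seed is not None else configs[0].seed
    streams = np.random.SeedSequence(master).spawn(len(configs) + 1)
    shared_rng = np.random.default_rng(streams[0])

    first = configs[0]
    baseline = shared_rng.normal(0.0, first.base_logmean_sd, size=first.n_taxa)
    planted_shared = _draw_planted(shared_rng, first) if shared_planted else None
    covariate_idx = np.sort(
        shared_rng.choice(first.n_taxa, size=first.n_covariate_taxa, replace=False)
    )

    cohorts: dict[str, tuple[AbundanceTable, SampleMetadata]] = {}
    truths: dict[str, GroundTruth] = {}
    for cfg, stream in zip(configs, streams[1:]):
        rng = np.random.default_rng(stream)
        planted = planted_shared if shared_planted else _draw_planted(rng, cfg)
        table, meta, truth = simulate_cohort(
            cfg, rng=rng, baseline=baseline, planted=planted, covariate_idx=covariate_idx
        )
        cohorts[cfg.cohort] = (table, meta)
        truths[cfg.cohort] = truth
    return CohortCollection(cohorts), truths
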