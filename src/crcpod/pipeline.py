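"""End-to-end study replica: simulate/load cohorts, screen, overlap, train
per-cohort POD models, score evaluation cohorts, evaluate.

The pipeline mirrors the study design: several training cohorts (the stand-
in for published external case/control cohorts) each yield a differential-
abundance screen; the screens are combined into one biomarker panel; one
forest is trained per training cohort on that panel; every model then
scores the held-out evaluation cohorts, giving per-model AUCs and pairwise
group POD comparisons.  All outputs are plain TSV/JSON and byte-identical
across reruns of the same configuration.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path
from typing import Literal, Optional

import pandas as pd
from pydantic import BaseModel, ConfigDict, model_validator

from . import __version__
from .diff_abundance import (
    case_control_labels,
    detected_taxa,
    overlap_biomarkers,
    wilcoxon_screen,
)
from .evaluation import compare_pod, roc_auc
from .io_tables import CohortCollection, read_abundance_table, read_metadata
from .pod_model import mda_importance, pod_scores, select_biomarkers, train_forest
from .synthetic_data import SyntheticConfig, simulate_cohort, simulate_multi_cohort


class CohortEntry(BaseModel):
    """One cohort: either a simulation config or a pair of file paths."""

    model_config = ConfigDict(extra="forbid")

    role: Literal["train", "test"]
    simulate: Optional[SyntheticConfig] = None
    abundance_path: Optional[str] = None
    metadata_path: Optional[str] = None

    @model_validator(mode="after")
    def _one_source(self) -> "CohortEntry":
        from_files = self.abundance_path is not None and self.metadata_path is not None
        if self.simulate is None and not from_files:
            raise ValueError("cohort needs either a simulate block or both file paths")
        if self.simulate is not None and (self.abundance_path or self.metadata_path):
            raise ValueError("cohort cannot mix simulate with file paths")
        return self

    def label(self, index: int) -> str:
        if self.simulate is not None:
            return self.simulate.cohort
        return Path(self.abundance_path).stem


class PipelineConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    cohorts: list[CohortEntry]
    alpha: float = 0.05
    pseudocount: float = 1e-05
    trees: int = 500
    overlap_mode: Literal["union", "intersection"] = "union"
    shared_planted: bool = True
    select_top_k: Optional[int] = None
    case_group: str = "CRC"
    control_group: str = "Control"
    seed: int = 0

    @model_validator(mode="after")
    def _roles(self) -> "PipelineConfig":
        roles = [c.role for c in self.cohorts]
        if "train" not in roles or "test" not in roles:
            raise ValueError("need at least one train and one test cohort")
        return self

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls.model_validate(raw)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_tsv(frame: pd.DataFrame, path: Path, index: bool = True) -> None:
    frame.to_csv(path, sep="\t", index=index, float_format="%.17g")


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def _materialize(config: PipelineConfig) -> CohortCollection:
    sim_entries = [(i, c) for i, c in enumerate(config.cohorts) if c.simulate is not None]
    file_entries = [(i, c) for i, c in enumerate(config.cohorts) if c.simulate is None]
    cohorts: dict = {}
    if len(sim_entries) >= 2:
        collection, _ = simulate_multi_cohort(
            [c.simulate for _, c in sim_entries],
            shared_planted=config.shared_planted,
            seed=config.seed,
        )
        cohorts.update(collection.cohorts)
    elif len(sim_entries) == 1:
        cfg = sim_entries[0][1].simulate.model_copy(update={"seed": config.seed})
        table, meta, _ = simulate_cohort(cfg)
        cohorts[cfg.cohort] = (table, meta)
    for i, entry in file_entries:
        table = read_abundance_table(entry.abundance_path)
        meta = read_metadata(entry.metadata_path).matched_to(table)
        cohorts[entry.label(i)] = (table, meta)
    return CohortCollection(cohorts).aligned()


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Run every stage and return the manifest (also written to
    ``manifest.json``).  Stage failures raise :class:`StageError` naming
    the stage; outputs written before the failure are listed as invalid in
    a partial manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    written: list[Path] = []
    labels_by_role = {"train": [], "test": []}
    for i, entry in enumerate(config.cohorts):
        labels_by_role[entry.role].append(entry.label(i))

    def stage(name):
        def wrap(fn, *args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-raised with stage context
                partial = {"status": "invalid", "failed_stage": name, "error": str(exc)}
                (out / "manifest.json").write_text(json.dumps(partial, indent=2, sort_keys=True))
                raise StageError(f"stage {name!r} failed: {exc}") from exc

        return wrap

    collection = stage("materialize")(_materialize, config)

    screens = []
    for label in labels_by_role["train"]:
        table, meta = collection.cohorts[label]
        labels = stage("screen")(
            case_control_labels, meta, config.case_group, config.control_group
        )
        screen = stage("screen")(
            wilcoxon_screen, table, labels, alpha=config.alpha, cohort=label
        )
        path = out / f"screen_{label}.tsv"
        _write_tsv(screen, path, index=False)
        written.append(path)
        screens.append(screen)

    test_tables = [collection.table(l) for l in labels_by_role["test"]]
    detected = detected_taxa(test_tables)
    panel = stage("overlap")(overlap_biomarkers, screens, detected, config.overlap_mode)

    models = {}
    for k, label in enumerate(labels_by_role["train"]):
        table, meta = collection.cohorts[label]
        labels = stage("train")(
            case_control_labels, meta, config.case_group, config.control_group
        )
        model_seed = config.seed + 1000 * (k + 1)
        model = stage("train")(
            train_forest, table, labels, panel,
            n_trees=config.trees, seed=model_seed, training_cohort=label,
        )
        imp = stage("importance")(mda_importance, model, table, labels, seed=model_seed)
        if config.select_top_k is not None:
            refined = select_biomarkers(imp, k=config.select_top_k)
            model = stage("train")(
                train_forest, table, labels, refined,
                n_trees=config.trees, seed=model_seed, training_cohort=label,
            )
            model.panel.importance = refined.importance
        else:
            model.panel.importance = {t: float(v) for t, v in imp.items()}
        path = out / f"model_{label}.json"
        model.save(path)
        written.append(path)
        models[label] = model

    panel_path = out / "panel.tsv"
    _write_tsv(panel.to_frame(), panel_path, index=False)
    written.append(panel_path)

    evaluation: dict = {"auc": {}, "pod_comparisons": {}}
    for test_label in labels_by_role["test"]:
        table, meta = collection.cohorts[test_label]
        groups = meta.groups
        for model_label, model in models.items():
            scores = stage("score")(pod_scores, model, table)
            path = out / f"pod_{model_label}_{test_label}.tsv"
            _write_tsv(scores, path)
            written.append(path)
            key = f"{model_label}:{test_label}"
            has_both = {config.case_group, config.control_group} <= set(groups)
            if has_both:
                mask = groups.isin([config.case_group, config.control_group])
                ids = groups.index[mask]
                res = roc_auc(
                    scores.loc[ids, "pod"].to_numpy(),
                    (groups.loc[ids] == config.case_group).to_numpy(),
                )
                evaluation["auc"][key] = round(float(res.auc), 12)
            by_group = {
                g: scores.loc[groups.index[groups == g], "pod"].to_numpy()
                for g in sorted(groups.unique())
                if (groups == g).sum() >= 2
            }
            if len(by_group) >= 2:
                comp = compare_pod(by_group)
                evaluation["pod_comparisons"][key] = [
                    {k: (round(v, 12) if isinstance(v, float) else v) for k, v in rec.items()}
                    for rec in comp.to_dict("records")
                ]

    eval_path = out / "eval.json"
    eval_path.write_text(json.dumps(evaluation, indent=2, sort_keys=True))
    written.append(eval_path)

    manifest = {
        "status": "ok",
        "crcpod_version": __version__,
        "seed": config.seed,
        "config": json.loads(config.model_dump_json()),
        "cohorts": {
            label: {
                "n_taxa": collection.table(label).n_taxa,
                "n_samples": collection.table(label).n_samples,
            }
            for label in collection.labels
        },
        "panel_size": len(panel),
        "outputs": {p.name: _sha256(p) for p in written},
        "elapsed_s": round(time.time() - t0, 3),
    }
    (out / "manifest.json").write_text(
        json.dumps({k: v for k, v in manifest.items() if k != "elapsed_s"}, indent=2, sort_keys=True)
    )
    return manifest
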