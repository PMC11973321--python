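"""Probability-of-disease (POD) tree-ensemble model.

The POD index summarizes a stool microbiome profile as the fraction of
randomly constructed decision trees that classify the sample as diseased:
an individual's likelihood of disease relative to being healthy, expressed
on [0, 1] (the unbounded vote odds ratio is exposed alongside).  The
ensemble is a random forest over the biomarker-panel taxa: each tree is
grown on a bootstrap resample, choosing at every node the best
Gini-impurity split among floor(sqrt(p)) randomly drawn panel taxa, to
purity (min leaf 1).  Out-of-bag (OOB) samples provide the internal error
estimate and the permutation (mean decrease accuracy) importance.

Split thresholds are placed AT observed values (rule ``x <= t`` goes left)
rather than at midpoints, which makes both the grown structure and every
prediction exactly invariant under strictly monotone per-taxon transforms
applied identically at train and score time — the property that lets the
model ignore the pseudo-count log-transform question entirely.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .diff_abundance import BiomarkerPanel
from .io_tables import AbundanceTable
from .preprocess import to_proportions

DEFAULT_TREES = 500


def _as_feature_scale(table: AbundanceTable) -> AbundanceTable:
    """Percent tables become proportions; proportion or log-transformed
    tables pass through (trees only consume order statistics, so any
    monotone feature scale is acceptable as long as train and score use
    the same one)."""
    return to_proportions(table) if table.scale == "percent" else table


@dataclass
class DecisionTree:
    """Flat-array binary tree.

    ``feature[i] == -1`` marks node i as a leaf; otherwise samples with
    ``x[feature] <= threshold`` go to ``left[i]``, the rest to ``right[i]``.
    ``counts[i]`` holds the (control, case) training counts reaching node i.
    ``oob_idx`` are the training-set rows left out of this tree's bootstrap.
    """

    feature: np.ndarray
    threshold: np.ndarray
    left: np.ndarray
    right: np.ndarray
    counts: np.ndarray
    oob_idx: np.ndarray

    @property
    def n_nodes(self) -> int:
        return self.feature.size

    def used_features(self) -> set[int]:
        return set(int(f) for f in self.feature if f >= 0)

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Per-sample class vote (0 control / 1 case); leaf ties vote
        control — the conservative risk call."""
        node = np.zeros(X.shape[0], dtype=np.int64)
        while True:
            f = self.feature[node]
            internal = f >= 0
            if not internal.any():
                break
            go_left = np.zeros(X.shape[0], dtype=bool)
            rows = np.flatnonzero(internal)
            go_left[rows] = X[rows, f[rows]] <= self.threshold[node[rows]]
            node = np.where(internal, np.where(go_left, self.left[node], self.right[node]), node)
        leaf_counts = self.counts[node]
        return (leaf_counts[:, 1] > leaf_counts[:, 0]).astype(np.int8)


def _grow_tree(
    X: np.ndarray,
    y: np.ndarray,
    rng: np.random.Generator,
    max_features: int,
    min_leaf: int,
) -> tuple[list, list, list, list, list]:
    """Grow one tree on (bootstrap) data; returns flat node arrays."""
    n, p = X.shape
    feature: list[int] = []
    threshold: list[float] = []
    left: list[int] = []
    right: list[int] = []
    counts: list[tuple[int, int]] = []

    def new_node(idx: np.ndarray) -> int:
        node_id = len(feature)
        n1 = int(y[idx].sum())
        feature.append(-1)
        threshold.append(0.0)
        left.append(-1)
        right.append(-1)
        counts.append((idx.size - n1, n1))
        return node_id

    root = new_node(np.arange(n))
    stack: list[tuple[int, np.ndarray]] = [(root, np.arange(n))]
    while stack:
        node_id, idx = stack.pop()
        ys = y[idx]
        n_node = idx.size
        n1 = int(ys.sum())
        if n1 == 0 or n1 == n_node or n_node < 2 * min_leaf:
            continue
        feats = rng.choice(p, size=max_features, replace=False)
        best_score = np.inf
        best_feat = -1
        best_pos = -1
        best_order: np.ndarray | None = None
        for f in feats:
            v = X[idx, f]
            order = np.argsort(v, kind="stable")
            sv = v[order]
            valid = sv[:-1] < sv[1:]
            if min_leaf > 1:
                valid[: min_leaf - 1] = False
                valid[n_node - min_leaf:] = False
            if not valid.any():
                continue
            c1 = np.cumsum(ys[order])[:-1].astype(float)
            nL = np.arange(1, n_node, dtype=float)
            nR = n_node - nL
            c1R = n1 - c1
            # weighted Gini: sum over sides of n_side * (1 - sum_k p_k^2)
            score = (nL - (c1**2 + (nL - c1) ** 2) / nL) + (
                nR - (c1R**2 + (nR - c1R) ** 2) / nR
            )
            score[~valid] = np.inf
            pos = int(np.argmin(score))
            if score[pos] < best_score:
                best_score = score[pos]
                best_feat = int(f)
                best_pos = pos
                best_order = order
        if best_feat < 0:
            continue  # all drawn features constant on this node: leaf
        sv = X[idx[best_order], best_feat]
        thr = float(sv[best_pos])
        go_left = X[idx, best_feat] <= thr
        left_idx, right_idx = idx[go_left], idx[~go_left]
        feature[node_id] = best_feat
        threshold[node_id] = thr
        lid = new_node(left_idx)
        rid = new_node(right_idx)
        left[node_id] = lid
        right[node_id] = rid
        stack.append((lid, left_idx))
        stack.append((rid, right_idx))
    return feature, threshold, left, right, counts


@dataclass
class PODModel:
    """Trained tree ensemble over a biomarker panel."""

    trees: list[DecisionTree]
    panel: BiomarkerPanel
    training_cohort: str
    oob_error: float
    seed: int

    @property
    def n_trees(self) -> int:
        return len(self.trees)

    def feature_matrix(self, table: AbundanceTable) -> np.ndarray:
        """Samples × panel-taxa feature matrix; panel taxa missing from the
        table are treated as zero abundance."""
        table = _as_feature_scale(table)
        aligned = table.data.reindex(index=self.panel.taxon_ids, fill_value=0.0)
        return aligned.to_numpy().T

    def votes(self, table: AbundanceTable) -> np.ndarray:
        """Per-tree class votes, samples × trees."""
        X = self.feature_matrix(table)
        return np.column_stack([t.predict(X) for t in self.trees])

    def pod(self, table: AbundanceTable) -> np.ndarray:
        """POD = fraction of trees voting disease, per sample."""
        return self.votes(table).mean(axis=1)

    # --- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "format": "crcpod-forest-v1",
            "seed": self.seed,
            "training_cohort": self.training_cohort,
            "oob_error": self.oob_error,
            "panel": {
                "taxon_ids": self.panel.taxon_ids,
                "source_cohorts": self.panel.source_cohorts,
                "importance": self.panel.importance,
            },
            "trees": [
                {
                    "feature": t.feature.tolist(),
                    "threshold": t.threshold.tolist(),
                    "left": t.left.tolist(),
                    "right": t.right.tolist(),
                    "counts": t.counts.tolist(),
                    "oob_idx": t.oob_idx.tolist(),
                }
                for t in self.trees
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PODModel":
        trees = [
            DecisionTree(
                feature=np.asarray(t["feature"], dtype=np.int64),
                threshold=np.asarray(t["threshold"], dtype=float),
                left=np.asarray(t["left"], dtype=np.int64),
                right=np.asarray(t["right"], dtype=np.int64),
                counts=np.asarray(t["counts"], dtype=np.int64),
                oob_idx=np.asarray(t["oob_idx"], dtype=np.int64),
            )
            for t in d["trees"]
        ]
        panel = BiomarkerPanel(
            d["panel"]["taxon_ids"],
            {k: list(v) for k, v in d["panel"].get("source_cohorts", {}).items()},
            d["panel"].get("importance"),
        )
        return cls(trees, panel, d.get("training_cohort", ""), float(d["oob_error"]), int(d["seed"]))

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "PODModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _resolve_labels(table: AbundanceTable, labels) -> tuple[AbundanceTable, np.ndarray]:
    if isinstance(labels, pd.Series):
        table = table.subset_samples(list(labels.index))
        y = labels.to_numpy(dtype=bool)
    else:
        y = np.asarray(labels, dtype=bool)
        if y.size != table.n_samples:
            raise ValueError("labels length does not match sample count")
    return table, y


def train_forest(
    table: AbundanceTable,
    labels,
    panel: BiomarkerPanel,
    n_trees: int = DEFAULT_TREES,
    seed: int = 0,
    min_leaf: int = 1,
    training_cohort: str = "",
) -> PODModel:
    """Train the POD forest on panel taxa.

    ``labels`` is a boolean case indicator (pd.Series indexed by sample id,
    or an array in table column order).  Each tree sees an n-out-of-n
    bootstrap; the aggregate OOB majority-vote error is recorded.  A fixed
    seed yields a bit-identical model.
    """
    table, y = _resolve_labels(table, labels)
    if y.all() or not y.any():
        raise ValueError("both classes must be present to train")
    missing = [t for t in panel.taxon_ids if t not in table.data.index]
    if missing:
        raise ValueError(f"panel taxa absent from table: {missing[:5]}")
    table = _as_feature_scale(table)
    X = table.data.loc[panel.taxon_ids].to_numpy().T  # samples × panel taxa
    y = y.astype(np.int8)
    n, p = X.shape
    mtry = max(1, int(np.sqrt(p)))

    rng = np.random.default_rng(seed)
    trees: list[DecisionTree] = []
    oob_votes = np.zeros((n, 2), dtype=np.int64)
    for _ in range(n_trees):
        boot = rng.integers(0, n, size=n)
        oob = np.setdiff1d(np.arange(n), boot)
        fa, th, lf, rt, ct = _grow_tree(X[boot], y[boot], rng, mtry, min_leaf)
        tree = DecisionTree(
            feature=np.asarray(fa, dtype=np.int64),
            threshold=np.asarray(th, dtype=float),
            left=np.asarray(lf, dtype=np.int64),
            right=np.asarray(rt, dtype=np.int64),
            counts=np.asarray(ct, dtype=np.int64),
            oob_idx=oob,
        )
        if oob.size:
            pred = tree.predict(X[oob])
            oob_votes[oob, 0] += pred == 0
            oob_votes[oob, 1] += pred == 1
        trees.append(tree)
    seen = oob_votes.sum(axis=1) > 0
    oob_pred = (oob_votes[:, 1] > oob_votes[:, 0]).astype(np.int8)
    oob_error = float((oob_pred[seen] != y[seen]).mean()) if seen.any() else float("nan")
    return PODModel(trees, panel, training_cohort, oob_error, seed)


def mda_importance(
    model: PODModel,
    table: AbundanceTable,
    labels,
    seed: int = 0,
) -> pd.Series:
    """Mean-decrease-accuracy importance per panel taxon.

    For every tree, each taxon's values are permuted among that tree's OOB
    samples and the drop in OOB accuracy is recorded; the importance is the
    mean drop over trees.  A taxon used by no split has importance exactly
    zero (its permutation cannot change any prediction, so no work is done
    for it).
    """
    table, y = _resolve_labels(table, labels)
    X = model.feature_matrix(table)
    y = y.astype(np.int8)
    rng = np.random.default_rng(seed)
    p = len(model.panel.taxon_ids)
    imp = np.zeros(p)
    for tree in model.trees:
        oob = tree.oob_idx
        if oob.size == 0:
            continue
        Xo, yo = X[oob], y[oob]
        base_acc = float((tree.predict(Xo) == yo).mean())
        for j in sorted(tree.used_features()):
            perm = rng.permutation(oob.size)
            Xp = Xo.copy()
            Xp[:, j] = Xo[perm, j]
            imp[j] += base_acc - float((tree.predict(Xp) == yo).mean())
    imp /= max(1, model.n_trees)
    return pd.Series(imp, index=pd.Index(model.panel.taxon_ids, name="taxon_id"), name="mda")


def select_biomarkers(
    importance: pd.Series,
    k: int | None = None,
    min_importance: float | None = None,
) -> BiomarkerPanel:
    """Restrict a panel to the most important taxa.

    Ordering is (importance descending, taxon id ascending) so ties break
    deterministically.  ``k`` beyond the panel size clamps with a warning.
    """
    if k is None and min_importance is None:
        raise ValueError("give k or min_importance")
    ordered = importance.sort_index().sort_values(ascending=False, kind="stable")
    if min_importance is not None:
        ordered = ordered[ordered >= min_importance]
    if k is not None:
        if k > ordered.size:
            import warnings

            warnings.warn(f"k={k} exceeds panel size {ordered.size}; clamping", stacklevel=2)
            k = ordered.size
        ordered = ordered.iloc[:k]
    if ordered.empty:
        raise ValueError("selection left an empty panel")
    return BiomarkerPanel(list(ordered.index), importance=dict(ordered))


def pod_scores(model: PODModel, table: AbundanceTable) -> pd.DataFrame:
    """POD per sample, with the derived vote odds (case votes / control
    votes; +inf at unanimity)."""
    pod = model.pod(table)
    with np.errstate(divide="ignore"):
        odds = np.where(pod < 1.0, pod / (1.0 - pod), np.inf)
    return pd.DataFrame(
        {"pod": pod, "vote_odds": odds},
        index=pd.Index(table.sample_ids, name="sample_id"),
    )
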