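"""Between-sample distances and classical PCoA.

Four dissimilarities are supported: Bray-Curtis, Jensen-Shannon distance
(square root of the base-2 symmetrized divergence, a metric bounded by 1),
and the Pearson / Spearman correlation distances 1 - r computed across taxa
within each sample pair.  Ordination is classical metric scaling: Gower
double-centering of -D²/2 followed by a symmetric eigendecomposition, with
negative eigenvalues (possible for non-Euclidean input) reported but
excluded from the variance-explained denominator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import braycurtis, jensenshannon
from scipy.stats import rankdata

from .io_tables import AbundanceTable
from .preprocess import to_proportions

METRICS = ("bray_curtis", "jensen_shannon", "pearson", "spearman")


@dataclass
class DistanceMatrix:
    """Symmetric zero-diagonal sample × sample dissimilarity matrix."""

    frame: pd.DataFrame
    metric: str

    def __post_init__(self) -> None:
        v = self.frame.to_numpy()
        if v.shape[0] != v.shape[1]:
            raise ValueError("distance matrix must be square")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if (v < -1e-12).any():
            raise ValueError("negative dissimilarities")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame.index)

    @property
    def values(self) -> np.ndarray:
        return self.frame.to_numpy()


@dataclass
class OrdinationResult:
    """PCoA embedding: samples × k coordinates plus the eigenspectrum."""

    coordinates: pd.DataFrame       # samples × axes
    eigenvalues: np.ndarray         # all eigenvalues, descending
    variance_explained: np.ndarray  # fraction per returned axis, over positive eigenvalues


def _correlation_distance(X: np.ndarray, sample_ids, spearman: bool) -> np.ndarray:
    if spearman:
        X = np.apply_along_axis(rankdata, 1, X)
    sd = X.std(axis=1)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        raise ValueError(
            "correlation distance undefined for constant profile(s): "
            + ", ".join(str(sample_ids[i]) for i in bad[:5])
        )
    r = np.corrcoef(X)
    d = 1.0 - r
    np.fill_diagonal(d, 0.0)
    return np.clip(d, 0.0, None)


def distance_matrix(table: AbundanceTable, metric: str) -> DistanceMatrix:
    """Pairwise sample dissimilarities under one of the four metrics."""
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; choose from {METRICS}")
    table = to_proportions(table)
    X = table.sample_matrix()          # samples × taxa
    ids = table.sample_ids
    n = len(ids)
    if n < 2:
        raise ValueError("need at least 2 samples")
    if metric in ("pearson", "spearman"):
        d = _correlation_distance(X, ids, spearman=(metric == "spearman"))
    else:
        func = braycurtis if metric == "bray_curtis" else (
            lambda u, v: jensenshannon(u, v, base=2.0)
        )
        d = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                d[i, j] = d[j, i] = func(X[i], X[j])
        d = np.nan_to_num(d)  # jensenshannon(x, x) can give nan from 0/0
    return DistanceMatrix(pd.DataFrame(d, index=ids, columns=ids), metric)


def pcoa(dist: DistanceMatrix, k: int = 2) -> OrdinationResult:
    """Classical principal coordinate analysis.

    Coordinates are eigenvectors scaled by the square roots of the positive
    eigenvalues.  Requested axes beyond the positive-eigenvalue count are
    truncated with a warning.  Axis signs are fixed by forcing the
    largest-magnitude coordinate on each axis positive, so embeddings are
    deterministic across runs and platforms.
    """
    D = dist.values
    n = D.shape[0]
    if n < 3:
        raise ValueError("PCoA needs at least 3 samples")
    if not 1 <= k <= n - 1:
        raise ValueError(f"k must be in [1, {n - 1}]")
    J = np.eye(n) - np.full((n, n), 1.0 / n)
    B = -0.5 * J @ (D**2) @ J
    B = (B + B.T) / 2.0
    eigvals, eigvecs = np.linalg.eigh(B)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    tol = max(abs(eigvals[0]), 1.0) * 1e-10
    n_pos = int((eigvals > tol).sum())
    if n_pos == 0:
        raise ValueError("no positive eigenvalues; degenerate distance matrix")
    if k > n_pos:
        warnings.warn(
            f"only {n_pos} positive eigenvalues; truncating from {k} axes", stacklevel=2
        )
        k = n_pos
    coords = eigvecs[:, :k] * np.sqrt(eigvals[:k])
    for a in range(k):
        if coords[np.argmax(np.abs(coords[:, a])), a] < 0:
            coords[:, a] = -coords[:, a]
    var_exp = eigvals[:k] / eigvals[:n_pos].sum()
    frame = pd.DataFrame(
        coords,
        index=pd.Index(dist.sample_ids, name="sample_id"),
        columns=[f"PC{i + 1}" for i in range(k)],
    )
    return OrdinationResult(frame, eigvals, var_exp)
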