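"""Feature selection and manifold reduction to a 1-D emotion trajectory.

Correlation-based feature selection (CFS) greedily grows a feature subset
maximizing the merit k*rcf / sqrt(k + k(k-1)*rff), where rcf is the mean
absolute feature-class correlation of the subset and rff its mean absolute
pairwise correlation — rewarding class relevance while penalizing
redundancy.  A leave-one-subject-out sign-consistency screen keeps only
features whose class correlation is stable across subjects
("subject-independent" features).

The selected features are embedded with Isomap: a symmetric k-NN Euclidean
graph, all-pairs geodesics by Dijkstra, then classical MDS of the squared
geodesic distances.  The leading coordinate, centered to zero mean, is the
emotion trajectory whose zero-crossing rate is analyzed downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import connected_components, dijkstra
from sklearn.neighbors import kneighbors_graph

logger = logging.getLogger(__name__)

__all__ = ["FeatureMatrix", "EmotionTrajectory", "cfs_merit", "cfs_select",
           "isomap_embed"]


@dataclass
class FeatureMatrix:
    """Windows x features matrix with class labels, optionally pooled
    across subjects (``subject_ids`` row-aligned with ``values``)."""

    values: np.ndarray
    feature_names: tuple[str, ...]
    labels: np.ndarray | None = None          # class per row (e.g. condition)
    subject_ids: np.ndarray | None = None
    timestamps: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.feature_names = tuple(self.feature_names)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.feature_names):
            raise ValueError("values must be (n_rows, n_features) matching names")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature matrix contains non-finite values")
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ValueError("feature names must be unique")
        for attr in ("labels", "subject_ids", "timestamps"):
            v = getattr(self, attr)
            if v is not None:
                v = np.asarray(v)
                if v.shape[0] != self.values.shape[0]:
                    raise ValueError(f"{attr} length mismatch")
                setattr(self, attr, v)

    def restrict(self, names: list[str]) -> "FeatureMatrix":
        idx = [self.feature_names.index(n) for n in names]
        return FeatureMatrix(self.values[:, idx], tuple(names), self.labels,
                             self.subject_ids, self.timestamps)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, label_col: str | None = None,
                   subject_col: str | None = None) -> "FeatureMatrix":
        meta_cols = [c for c in (label_col, subject_col) if c]
        feats = df.drop(columns=meta_cols)
        return cls(
            feats.to_numpy(float), tuple(feats.columns),
            df[label_col].to_numpy() if label_col else None,
            df[subject_col].to_numpy() if subject_col else None,
        )


@dataclass
class EmotionTrajectory:
    """Zero-mean 1-D series summarizing emotional state over time."""

    values: np.ndarray
    timestamps: np.ndarray
    zero_mean: bool = True

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if self.zero_mean:
            sd = self.values.std()
            if sd > 0 and abs(self.values.mean()) > 1e-9 * sd:
                raise ValueError("trajectory marked zero_mean but has nonzero mean")


# --------------------------------------------------------------------- CFS

def cfs_merit(k: int, r_cf: float, r_ff: float) -> float:
    """Merit of a k-feature subset: k*r_cf / sqrt(k + k(k-1)*r_ff)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    return k * r_cf / np.sqrt(k + k * (k - 1) * r_ff)


def _safe_abs_corr(a: np.ndarray, b: np.ndarray) -> float:
    # constant columns carry no information: correlation treated as 0
    if a.std() == 0 or b.std() == 0:
        return 0.0
    return abs(float(np.corrcoef(a, b)[0, 1]))


def _signed_corr(a: np.ndarray, b: np.ndarray) -> float:
    if a.std() == 0 or b.std() == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def _loso_consistent(fm: FeatureMatrix, y: np.ndarray,
                     min_fraction: float) -> np.ndarray:
    """Features whose leave-one-subject-out class-correlation sign is stable."""
    subjects = np.unique(fm.subject_ids)
    if subjects.size < 2:
        return np.ones(len(fm.feature_names), dtype=bool)
    signs = np.zeros((subjects.size, len(fm.feature_names)))
    for s_i, s in enumerate(subjects):
        keep = fm.subject_ids != s
        if np.unique(y[keep]).size < 2:
            continue
        for f in range(len(fm.feature_names)):
            signs[s_i, f] = np.sign(_signed_corr(fm.values[keep, f], y[keep]))
    ok = np.zeros(len(fm.feature_names), dtype=bool)
    for f in range(len(fm.feature_names)):
        nz = signs[:, f][signs[:, f] != 0]
        if nz.size == 0:
            continue
        frac = max((nz > 0).mean(), (nz < 0).mean())
        ok[f] = frac >= min_fraction
    return ok


def cfs_select(features: FeatureMatrix, n_select: int = 15,
               consistency: float = 0.8) -> list[str]:
    """Greedy forward CFS; returns the selected feature names in order.

    Class labels are coded 0/1 and correlations are Pearson.  When subject
    ids are present, features failing the leave-one-subject-out sign-
    consistency screen (stable sign in >= ``consistency`` of leave-outs)
    are deprioritized: they are appended only if the screened pool is
    smaller than ``n_select``.  Ties break by column order.
    """
    if features.labels is None:
        raise ValueError("cfs_select requires class labels")
    if n_select < 1 or n_select > len(features.feature_names):
        raise ValueError(f"n_select must be in [1, {len(features.feature_names)}]")
    classes = np.unique(features.labels)
    if classes.size != 2:
        raise ValueError(f"expected a binary class variable, got {classes.size} classes")
    y = (features.labels == classes[1]).astype(float)

    names = list(features.feature_names)
    X = features.values
    r_cf = np.array([_safe_abs_corr(X[:, j], y) for j in range(X.shape[1])])

    pool = list(range(X.shape[1]))
    if features.subject_ids is not None:
        ok = _loso_consistent(features, y, consistency)
        screened = [j for j in pool if ok[j]]
        if len(screened) >= n_select:
            pool = screened
        else:
            logger.warning(
                "subject-consistency screen kept %d < %d features; backfilling",
                len(screened), n_select,
            )
            pool = screened + [j for j in pool if not ok[j]]

    # pairwise |corr| computed lazily between candidates and selected set
    abs_corr_cache: dict[tuple[int, int], float] = {}

    def ff(i: int, j: int) -> float:
        key = (min(i, j), max(i, j))
        if key not in abs_corr_cache:
            abs_corr_cache[key] = _safe_abs_corr(X[:, i], X[:, j])
        return abs_corr_cache[key]

    selected: list[int] = []
    remaining = list(pool)
    while len(selected) < n_select and remaining:
        best_j, best_merit = None, -np.inf
        for j in remaining:
            cand = selected + [j]
            k = len(cand)
            rcf_bar = r_cf[cand].mean()
            if k == 1:
                rff_bar = 0.0
            else:
                pairs = [ff(a, b) for ai, a in enumerate(cand) for b in cand[ai + 1:]]
                rff_bar = float(np.mean(pairs))
            m = cfs_merit(k, rcf_bar, rff_bar)
            if m > best_merit:  # strict: ties keep earliest column
                best_j, best_merit = j, m
        selected.append(best_j)
        remaining.remove(best_j)
    return [names[j] for j in selected]


# ------------------------------------------------------------------ Isomap

def _classical_mds_1d(D2: np.ndarray) -> np.ndarray:
    """Leading coordinate of classical MDS of squared distances."""
    n = D2.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ D2 @ J
    B = (B + B.T) / 2.0
    w, v = np.linalg.eigh(B)
    lam, vec = w[-1], v[:, -1]
    if lam <= 0:  # degenerate cloud: all points coincide
        return np.zeros(n)
    return np.sqrt(lam) * vec


def isomap_embed(
    features: FeatureMatrix,
    k_neighbors: int = 10,
    timestamps: np.ndarray | None = None,
) -> EmotionTrajectory:
    """1-D Isomap embedding of the rows of ``features``.

    Builds a symmetric k-NN Euclidean graph, computes all-pairs geodesics
    with Dijkstra, and applies classical MDS to the squared geodesics.  If
    the graph is disconnected, ``k_neighbors`` is incremented (logged)
    until it connects, capped at n_rows - 1.  The output is centered to
    zero mean and sign-fixed so its first nonzero value is positive.
    """
    X = features.values
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least 2 rows to embed")
    k = int(min(max(1, k_neighbors), n - 1))

    while True:
        W = kneighbors_graph(X, n_neighbors=k, mode="distance")
        W = W.maximum(W.T)  # symmetric neighborhood graph
        n_comp, _ = connected_components(W, directed=False)
        if n_comp == 1 or k >= n - 1:
            break
        k += 1
        logger.info("neighborhood graph disconnected; raising k_neighbors to %d", k)
    if n_comp > 1:
        raise ValueError("neighborhood graph disconnected even at k = n-1 "
                         "(duplicate points at infinite distance?)")

    G = dijkstra(W, directed=False)
    coord = _classical_mds_1d(G ** 2)
    coord = coord - coord.mean()
    nz = np.flatnonzero(np.abs(coord) > 1e-12 * max(1.0, np.abs(coord).max()))
    if nz.size and coord[nz[0]] < 0:
        coord = -coord

    if timestamps is None:
        timestamps = (features.timestamps if features.timestamps is not None
                      else np.arange(n, dtype=float))
    return EmotionTrajectory(coord, timestamps)
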