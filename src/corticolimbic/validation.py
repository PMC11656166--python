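"""Cluster-validation indices and the k-selection report.

The number of clusters is chosen by evaluating four classical indices on the
embedding coordinates for every candidate cut of the dendrogram:

* Calinski-Harabasz: between-cluster vs within-cluster variance,
  [tr(B)/(k-1)] / [tr(W)/(n-k)] — higher is better.
* Davies-Bouldin: mean over clusters of the worst (s_i + s_j) / d(c_i, c_j)
  — lower is better.
* Dunn: minimum single-link between-cluster distance divided by the maximum
  cluster diameter — higher is better.
* Silhouette: mean of (b - a) / max(a, b) over points — higher is better.

Degenerate geometry (zero within-scatter, coincident centroids) yields an
infinite sentinel, reported with a flag rather than silently dropped.  The
recommended k is the majority vote over the four per-index optima, ties
broken toward smaller k; a manual override is the faithful path when the
indices are read jointly with prior knowledge.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist, pdist, squareform

from .forest import ClusterSolution, Embedding, cut_tree

logger = logging.getLogger("corticolimbic")

INDEX_DIRECTIONS = {
    "calinski_harabasz": "higher",
    "davies_bouldin": "lower",
    "dunn": "higher",
    "silhouette": "higher",
}


def _check_labels(X: np.ndarray, labels: np.ndarray) -> list[np.ndarray]:
    X = np.asarray(X, float)
    labels = np.asarray(labels)
    if len(labels) != len(X):
        raise ValueError("labels and coordinates disagree in length")
    groups = [np.flatnonzero(labels == lab) for lab in np.unique(labels)]
    if any(len(g) == 0 for g in groups):
        raise ValueError("empty cluster")
    k = len(groups)
    if not (2 <= k < len(X)):
        raise ValueError(f"need 2 <= k < n (got k={k}, n={len(X)})")
    return groups


def calinski_harabasz(X: np.ndarray, labels: np.ndarray) -> float:
    """Variance-ratio criterion about cluster centroids; +inf if W is zero."""
    X = np.asarray(X, float)
    groups = _check_labels(X, labels)
    k, n = len(groups), len(X)
    overall = X.mean(axis=0)
    between = sum(len(g) * float(((X[g].mean(axis=0) - overall) ** 2).sum())
                  for g in groups)
    within = sum(float(((X[g] - X[g].mean(axis=0)) ** 2).sum()) for g in groups)
    if within == 0.0:
        return np.inf
    return (between / (k - 1)) / (within / (n - k))


def davies_bouldin(X: np.ndarray, labels: np.ndarray) -> float:
    """Mean worst-pair similarity (s_i + s_j)/d(c_i, c_j); inf on coincident centroids."""
    X = np.asarray(X, float)
    groups = _check_labels(X, labels)
    cents = np.stack([X[g].mean(axis=0) for g in groups])
    spread = np.array([float(cdist(X[g], cents[i][None]).mean())
                       for i, g in enumerate(groups)])
    cd = cdist(cents, cents)
    k = len(groups)
    ratios = np.zeros(k)
    for i in range(k):
        vals = []
        for j in range(k):
            if j == i:
                continue
            if cd[i, j] == 0.0:
                logger.warning("davies_bouldin: coincident centroids (%d, %d)", i, j)
                vals.append(np.inf)
            else:
                vals.append((spread[i] + spread[j]) / cd[i, j])
        ratios[i] = max(vals)
    return float(ratios.mean())


def dunn_index(X: np.ndarray, labels: np.ndarray) -> float:
    """Min between-cluster single-link distance over max cluster diameter."""
    X = np.asarray(X, float)
    groups = _check_labels(X, labels)
    diam = 0.0
    for g in groups:
        if len(g) > 1:
            diam = max(diam, float(pdist(X[g]).max()))
    min_sep = np.inf
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            min_sep = min(min_sep, float(cdist(X[groups[i]], X[groups[j]]).min()))
    if diam == 0.0:
        logger.warning("dunn_index: all clusters are single points or duplicates")
        return np.inf if min_sep > 0 else np.nan
    return min_sep / diam


def silhouette(X: np.ndarray, labels: np.ndarray) -> float:
    """Mean silhouette width; singleton points score 0, as do a=b=0 ties."""
    X = np.asarray(X, float)
    groups = _check_labels(X, labels)
    D = squareform(pdist(X))
    labels = np.asarray(labels)
    scores = np.zeros(len(X))
    for idx in range(len(X)):
        own = np.flatnonzero(labels == labels[idx])
        if len(own) == 1:
            scores[idx] = 0.0
            continue
        a = D[idx, own[own != idx]].mean()
        b = min(D[idx, g].mean() for g in groups
                if labels[g[0]] != labels[idx])
        denom = max(a, b)
        scores[idx] = 0.0 if denom == 0.0 else (b - a) / denom
    return float(scores.mean())


_INDEX_FUNCS = {
    "calinski_harabasz": calinski_harabasz,
    "davies_bouldin": davies_bouldin,
    "dunn": dunn_index,
    "silhouette": silhouette,
}


@dataclass
class IndexTable:
    """Per-k validation-index table with directions and the recommendation."""

    table: pd.DataFrame          # index: k; columns: the four indices
    recommended_k: int
    votes: dict[str, int]        # per-index argbest k
    directions: dict[str, str]

    def to_csv(self, path) -> None:
        out = self.table.copy()
        out.loc["direction"] = [self.directions[c] for c in out.columns]
        out.to_csv(path)


def k_selection_report(embedding: Embedding | np.ndarray, solution: ClusterSolution,
                       k_range: tuple[int, int]) -> IndexTable:
    """Evaluate all four indices on every dendrogram cut in ``k_range``.

    Recommendation: each index votes for its best k (respecting direction,
    infinite sentinels excluded); the winner is the modal vote, ties broken
    toward smaller k.
    """
    coords = embedding.coords if isinstance(embedding, Embedding) else np.asarray(embedding)
    k_lo, k_hi = int(k_range[0]), int(k_range[1])
    n = len(coords)
    if not (2 <= k_lo <= k_hi <= n - 1):
        raise ValueError(f"k_range {k_range} must lie within [2, {n - 1}]")
    rows = {}
    for k in range(k_lo, k_hi + 1):
        labels = cut_tree(solution, k)
        rows[k] = {name: fn(coords, labels) for name, fn in _INDEX_FUNCS.items()}
    table = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    table.index.name = "k"

    votes: dict[str, int] = {}
    for name, direction in INDEX_DIRECTIONS.items():
        col = table[name].replace([np.inf, -np.inf], np.nan).dropna()
        if col.empty:
            logger.warning("k_selection_report: index %s degenerate for all k", name)
            continue
        votes[name] = int(col.idxmin() if direction == "lower" else col.idxmax())
    counts = pd.Series(list(votes.values())).value_counts()
    top = counts[counts == counts.max()].index.min()
    rec = int(top)
    logger.info("k_selection_report: votes=%s -> recommended k=%d", votes, rec)
    return IndexTable(table=table, recommended_k=rec, votes=votes,
                      directions=dict(INDEX_DIRECTIONS))
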