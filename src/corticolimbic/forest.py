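"""Unsupervised random-forest dissimilarity, classical MDS and UPGMA clustering.

The dissimilarity between two subjects is derived from random-forest
proximity: a classification forest is trained to separate the real feature
rows from a synthetic contrast sample in which each column is independently
bootstrapped (destroying between-column dependence while preserving
marginals).  The proximity of two real subjects is the fraction of trees in
which they share a terminal node; dissimilarity = sqrt(1 - proximity).
Hyperparameters (mtry = features per split, nodesize = minimum leaf size) are
tuned by out-of-bag error, and the stability of the dissimilarity matrix is
assessed by re-running the forest with fresh seeds.

The dissimilarity matrix is reduced with classical (Torgerson) MDS — double
centering of -D^2/2 followed by an eigendecomposition — and the leading
coordinates are clustered with average-linkage (UPGMA) agglomerative
clustering on Euclidean distances.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import adjusted_rand_score

logger = logging.getLogger("corticolimbic")


@dataclass
class RfParams:
    """Forest hyperparameters: tree count, mtry, nodesize, seed."""

    n_trees: int
    mtry: int
    nodesize: int
    seed: int

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.mtry < 1:
            raise ValueError("mtry must be >= 1")
        if self.nodesize < 1:
            raise ValueError("nodesize must be >= 1")


@dataclass
class DissimilarityMatrix:
    """Symmetric n x n subject dissimilarity with provenance."""

    values: np.ndarray
    subject_ids: list[str]
    params: RfParams

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.subject_ids, columns=self.subject_ids)


@dataclass
class Embedding:
    """Classical-MDS coordinates plus the full eigenvalue spectrum."""

    coords: np.ndarray           # n x d
    eigenvalues: np.ndarray      # all eigenvalues, descending
    subject_ids: list[str]

    @property
    def d(self) -> int:
        return self.coords.shape[1]


@dataclass
class ClusterSolution:
    """UPGMA merge history with deterministic per-k cuts.

    ``linkage`` is a scipy linkage matrix; labels for a cut are re-indexed so
    that label 1 is the largest cluster (size-descending, ties by first
    occurrence), making outputs reproducible.
    """

    linkage: np.ndarray
    subject_ids: list[str]
    chosen_k: int | None = None
    labels_by_k: dict[int, np.ndarray] = field(default_factory=dict)

    @property
    def n(self) -> int:
        return len(self.subject_ids)

    def cut(self, k: int) -> np.ndarray:
        return cut_tree(self, k)

    def cophenetic_heights(self) -> np.ndarray:
        return hierarchy.cophenet(self.linkage)


# ---------------------------------------------------------------------------
# Contrast sample and forest dissimilarity
# ---------------------------------------------------------------------------

def make_contrast_sample(X: np.ndarray, seed: int) -> np.ndarray:
    """Synthetic contrast matrix: independent bootstrap of each column.

    Each synthetic column is a with-replacement resample of the corresponding
    real column, preserving marginal distributions but destroying
    between-column dependence (the standard unsupervised-forest contrast
    class construction).
    """
    X = np.asarray(X, float)
    n = X.shape[0]
    if n < 2:
        raise ValueError("need >= 2 rows to build a contrast sample")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=X.shape)
    return np.take_along_axis(X, idx, axis=0)


def _fit_real_vs_contrast(X: np.ndarray, contrast: np.ndarray, params: RfParams,
                          oob_score: bool = False) -> RandomForestClassifier:
    Xy = np.vstack([X, contrast])
    y = np.concatenate([np.zeros(len(X)), np.ones(len(contrast))])
    clf = RandomForestClassifier(
        n_estimators=params.n_trees,
        max_features=min(params.mtry, X.shape[1]),
        min_samples_leaf=params.nodesize,
        bootstrap=True,
        oob_score=oob_score,
        random_state=params.seed,
        n_jobs=1,
    )
    with warnings.catch_warnings():
        # some trees may miss one class OOB on tiny samples; harmless here
        warnings.simplefilter("ignore", UserWarning)
        clf.fit(Xy, y)
    return clf


def _proximity(clf: RandomForestClassifier, X: np.ndarray,
               oob_only: bool = False) -> np.ndarray:
    """Fraction of trees in which each pair of real rows shares a leaf.

    With ``oob_only`` a pair is counted only over trees where both rows are
    out of bag (per-pair denominators); otherwise all trees count, which is
    the more stable estimator at desk-scale tree counts.
    """
    leaves = clf.apply(X)                      # n x n_trees
    n, n_trees = leaves.shape
    prox = np.zeros((n, n), float)
    if not oob_only:
        for t in range(n_trees):
            col = leaves[:, t]
            prox += col[:, None] == col[None, :]
        return prox / n_trees
    denom = np.zeros((n, n), float)
    all_samples = clf.estimators_samples_
    for t in range(n_trees):
        sampled = np.asarray(all_samples[t])
        oob_mask = np.ones(n, bool)            # real rows occupy training indices 0..n-1
        oob_mask[np.unique(sampled[sampled < n])] = False
        col = leaves[:, t]
        same = (col[:, None] == col[None, :]) & np.outer(oob_mask, oob_mask)
        prox += same
        denom += np.outer(oob_mask, oob_mask)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(denom > 0, prox / denom, 0.0)
    np.fill_diagonal(out, 1.0)
    return out


def rf_dissimilarity(X: np.ndarray | pd.DataFrame, params: RfParams, *,
                     oob_only: bool = False, sqrt_transform: bool = True,
                     ) -> DissimilarityMatrix:
    """Random-forest dissimilarity matrix over the real rows of X.

    Trains a real-vs-contrast forest, computes pairwise proximities of the
    real rows and returns sqrt(1 - proximity) (or 1 - proximity with
    ``sqrt_transform=False``).  Reproducible given ``params.seed``.
    """
    if params.n_trees < 50:
        logger.warning("rf_dissimilarity: %d trees is small for stable proximities",
                       params.n_trees)
    ids = list(X.index) if isinstance(X, pd.DataFrame) else [str(i) for i in range(len(X))]
    Xa = np.asarray(X, float)
    contrast = make_contrast_sample(Xa, seed=params.seed + 1)
    clf = _fit_real_vs_contrast(Xa, contrast, params)
    prox = _proximity(clf, Xa, oob_only=oob_only)
    prox = np.clip((prox + prox.T) / 2.0, 0.0, 1.0)
    np.fill_diagonal(prox, 1.0)
    diss = np.sqrt(1.0 - prox) if sqrt_transform else 1.0 - prox
    np.fill_diagonal(diss, 0.0)
    return DissimilarityMatrix(values=diss, subject_ids=ids, params=params)


def tune_rf(X: np.ndarray | pd.DataFrame, mtry_grid: list[int], nodesize_grid: list[int],
            n_trees: int, seed: int) -> RfParams:
    """Grid search over (mtry, nodesize) by out-of-bag misclassification error.

    The same contrast sample is reused across the grid for comparability;
    ties break toward smaller mtry, then smaller nodesize.
    """
    if not mtry_grid or not nodesize_grid:
        raise ValueError("hyperparameter grids must be non-empty")
    Xa = np.asarray(X, float)
    contrast = make_contrast_sample(Xa, seed=seed + 1)
    best: tuple[float, int, int] | None = None
    for mtry in sorted(set(mtry_grid)):
        for nodesize in sorted(set(nodesize_grid)):
            params = RfParams(n_trees=n_trees, mtry=mtry, nodesize=nodesize, seed=seed)
            clf = _fit_real_vs_contrast(Xa, contrast, params, oob_score=True)
            err = 1.0 - float(clf.oob_score_)
            key = (err, mtry, nodesize)
            if best is None or key < best:
                best = key
    err, mtry, nodesize = best
    logger.info("tune_rf: selected mtry=%d nodesize=%d (OOB error %.4f)", mtry, nodesize, err)
    return RfParams(n_trees=n_trees, mtry=mtry, nodesize=nodesize, seed=seed)


@dataclass
class StabilityReport:
    """Element-wise dissimilarity differences and label agreement across runs."""

    mean_abs_diff: np.ndarray     # per run
    max_abs_diff: np.ndarray      # per run
    ari_vs_reference: np.ndarray  # per run
    n_runs: int

    def summary(self) -> dict[str, float]:
        return {
            "mean_abs_diff": float(self.mean_abs_diff.mean()),
            "max_abs_diff": float(self.max_abs_diff.max()),
            "min_ari": float(self.ari_vs_reference.min()),
            "n_runs": self.n_runs,
        }


def stability_assessment(X: np.ndarray | pd.DataFrame, params: RfParams, n_runs: int,
                         *, k: int = 4, mds_dims: int = 3) -> StabilityReport:
    """Re-run the forest with fresh seeds and compare to the reference run.

    Reports the distribution of element-wise absolute differences between the
    reference dissimilarity matrix and each re-run, plus the adjusted Rand
    index of the downstream cluster labels against the reference labels.
    """
    if n_runs < 2:
        raise ValueError("n_runs must be >= 2")
    ref = rf_dissimilarity(X, params)
    ref_labels = cut_tree(average_linkage(classical_mds(ref, mds_dims)), k)
    mean_d, max_d, aris = [], [], []
    for r in range(1, n_runs + 1):
        run_params = RfParams(params.n_trees, params.mtry, params.nodesize,
                              seed=params.seed + r)
        run = rf_dissimilarity(X, run_params)
        diff = np.abs(run.values - ref.values)
        iu = np.triu_indices_from(diff, k=1)
        mean_d.append(float(diff[iu].mean()))
        max_d.append(float(diff[iu].max()))
        labels = cut_tree(average_linkage(classical_mds(run, mds_dims)), k)
        aris.append(adjusted_rand_score(ref_labels, labels))
    return StabilityReport(np.array(mean_d), np.array(max_d), np.array(aris), n_runs)


# ---------------------------------------------------------------------------
# Classical MDS
# ---------------------------------------------------------------------------

def classical_mds(D: DissimilarityMatrix | np.ndarray, d: int) -> Embedding:
    """Torgerson scaling: double-center -D^2/2, eigendecompose, keep top d.

    Coordinates are eigenvectors scaled by the square roots of the top-d
    positive eigenvalues.  Columns are ordered by descending eigenvalue and
    sign-fixed (first element of largest magnitude made positive) so outputs
    are reproducible.  If fewer than d eigenvalues are positive, only the
    available dimensions are returned, with a warning.
    """
    if d < 1:
        raise ValueError("d must be >= 1")
    if isinstance(D, DissimilarityMatrix):
        ids = D.subject_ids
        Dm = D.values
    else:
        Dm = np.asarray(D, float)
        ids = [str(i) for i in range(len(Dm))]
    n = Dm.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (Dm ** 2) @ J
    B = (B + B.T) / 2.0
    eigval, eigvec = np.linalg.eigh(B)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    tol = max(n, 1) * np.finfo(float).eps * max(abs(eigval[0]), 1.0)
    n_pos = int((eigval > tol).sum())
    keep = min(d, n_pos)
    if keep < d:
        logger.warning("classical_mds: only %d positive eigenvalue(s); "
                       "returning %d of %d requested dimensions", n_pos, keep, d)
    coords = eigvec[:, :keep] * np.sqrt(eigval[:keep])
    for j in range(coords.shape[1]):
        col = coords[:, j]
        lead = col[np.argmax(np.abs(col))]
        if lead < 0:
            coords[:, j] = -col
    return Embedding(coords=coords, eigenvalues=eigval, subject_ids=ids)


# ---------------------------------------------------------------------------
# Average-linkage (UPGMA) clustering
# ---------------------------------------------------------------------------

def average_linkage(embedding: Embedding | np.ndarray) -> ClusterSolution:
    """UPGMA on Euclidean distances between embedded coordinates."""
    if isinstance(embedding, Embedding):
        coords = embedding.coords
        ids = embedding.subject_ids
    else:
        coords = np.asarray(embedding, float)
        ids = [str(i) for i in range(len(coords))]
    if len(coords) < 2:
        raise ValueError("need >= 2 points to cluster")
    Z = hierarchy.linkage(pdist(coords), method="average")
    return ClusterSolution(linkage=Z, subject_ids=ids)


def cut_tree(solution: ClusterSolution, k: int) -> np.ndarray:
    """Cut the dendrogram into k groups with size-descending label ids.

    Returns integer labels 1..k where label 1 is the largest cluster (ties
    broken by first subject occurrence).
    """
    n = solution.n
    if not (1 <= k <= n):
        raise ValueError(f"k={k} out of range [1, {n}]")
    raw = hierarchy.fcluster(solution.linkage, t=k, criterion="maxclust")
    if len(np.unique(raw)) != k:
        # maxclust can undershoot with tied heights; fall back to cutting at rank
        raw = hierarchy.cut_tree(solution.linkage, n_clusters=k).ravel() + 1
    sizes = pd.Series(raw).value_counts()
    first_seen = {lab: int(np.argmax(raw == lab)) for lab in sizes.index}
    order = sorted(sizes.index, key=lambda lab: (-sizes[lab], first_seen[lab]))
    remap = {old: new for new, old in enumerate(order, start=1)}
    labels = np.array([remap[lab] for lab in raw], dtype=int)
    solution.labels_by_k[k] = labels
    return labels


def squareform_from_coords(coords: np.ndarray) -> np.ndarray:
    """Euclidean distance matrix of a coordinate set (test/diagnostic helper)."""
    return squareform(pdist(np.asarray(coords, float)))
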