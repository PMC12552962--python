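"""Clustering of term-similarity matrices.

Three methods over the same substrate (a symmetric similarity matrix S
in [0, 1], distance D = 1 - S):

* **binary cut** — recursive two-way partitioning.  The node score of a
  submatrix is the mean of its off-diagonal entries (1 for a 1x1
  block); a node whose score reaches the cutoff, or that is smaller
  than ``min_split``, is emitted as a cluster, otherwise its terms are
  split in two (2-medoid PAM or 2-means) and both halves recurse.
* **hierarchical** — agglomerative clustering on D with average or
  complete linkage; when k is not given it is chosen to maximise the
  mean silhouette width over k = 2..min(n-1, 25), ties to the smaller k.
* **combined** — binary cut followed by conditional hierarchical
  refinement: every binary-cut cluster whose within-cluster mean
  similarity falls below ``refine_threshold`` or whose size exceeds
  ``max_cluster_size`` is re-clustered on its own submatrix.  Tight,
  small clusters pass through untouched, so refinement behaves between
  the two parent methods.

Estimators follow scikit-learn conventions (``fit`` on a precomputed
square similarity matrix, ``labels_`` 0-based, ``n_clusters_``); the
module-level functions wrap them into 1-based :class:`ClusterAssignment`
records keyed by term id.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage as scipy_linkage
from scipy.spatial.distance import pdist, squareform
from scipy.stats import wilcoxon
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .errors import InputError
from .similarity import SimilarityMatrix

logger = logging.getLogger(__name__)

_ATOL = 1e-12
MAX_SILHOUETTE_K = 25


# -- validation ---------------------------------------------------------------

def _as_similarity_array(S) -> tuple[np.ndarray, list[str]]:
    """Accept a SimilarityMatrix or a raw square array; validate contract."""
    if isinstance(S, SimilarityMatrix):
        S.validate()
        return S.values, list(S.term_ids)
    arr = np.asarray(S, dtype=float)
    if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
        raise InputError(f"similarity matrix must be square, got {arr.shape}")
    if not np.allclose(arr, arr.T, atol=1e-8):
        raise InputError("similarity matrix is not symmetric")
    if arr.min() < -_ATOL or arr.max() > 1 + _ATOL:
        raise InputError("similarity values outside [0, 1]")
    ids = [f"item{i}" for i in range(arr.shape[0])]
    return arr, ids


def _off_diag_mean(sub: np.ndarray) -> float:
    n = sub.shape[0]
    if n <= 1:
        return 1.0
    return float((sub.sum() - np.trace(sub)) / (n * (n - 1)))


# -- 2-way partitioners -------------------------------------------------------

def _pam2(S_sub: np.ndarray) -> np.ndarray:
    """Exhaustive 2-medoid partition of the rows of a similarity block.

    Partitioning operates on row *profiles* (Euclidean distance between
    similarity rows): two items in the same latent block see the rest
    of the matrix the same way and therefore stay together, even when
    their mutual similarity to both medoids is comparable.
    Deterministic: scans all medoid pairs, ties broken by the first
    (lexicographically smallest) index pair; points tie to the first
    medoid.
    """
    D = squareform(pdist(S_sub), checks=False)
    n = D.shape[0]
    best_cost = np.inf
    best_pair = (0, 1)
    for i in range(n - 1):
        costs = np.minimum(D[:, i][:, None], D[:, i + 1:]).sum(axis=0)
        j_rel = int(np.argmin(costs))
        if costs[j_rel] < best_cost - _ATOL:
            best_cost = costs[j_rel]
            best_pair = (i, i + 1 + j_rel)
    i, j = best_pair
    return np.where(D[:, j] < D[:, i], 1, 0)


def _kmeans2(S_sub: np.ndarray, seed: int) -> np.ndarray:
    km = KMeans(n_clusters=2, n_init=10, random_state=seed)
    return km.fit_predict(S_sub)


@dataclass
class BinaryCutParams:
    """Tunables of the binary-cut recursion."""

    cutoff: float = 0.85
    partitioner: str = "pam2"
    min_split: int = 2
    seed: int = 1

    def __post_init__(self) -> None:
        if not 0.0 <= self.cutoff <= 1.0:
            raise InputError(f"cutoff must be in [0, 1], got {self.cutoff}")
        if self.min_split < 2:
            raise InputError(f"min_split must be >= 2, got {self.min_split}")
        if self.partitioner not in ("pam2", "kmeans2"):
            raise InputError(f"unknown partitioner {self.partitioner!r}")


# -- estimators ---------------------------------------------------------------

class BinaryCutClustering(ClusterMixin, BaseEstimator):
    """Recursive binary-cut clustering of a precomputed similarity matrix.

    Parameters
    ----------
    cutoff : float, default 0.85
        Accept a node as one cluster when its mean off-diagonal
        similarity reaches this value.
    partitioner : {"pam2", "kmeans2"}, default "pam2"
        Two-way split rule applied to the node's similarity rows; pam2
        is an exhaustive 2-medoid search on row-profile distances
        (deterministic), kmeans2 is seeded k-means on the rows.
    min_split : int, default 2
        Nodes smaller than this are emitted without splitting.
    random_state : int, default 1
        Seed for the kmeans2 partitioner.

    Attributes
    ----------
    labels_ : ndarray of shape (n,)
        0-based dense cluster labels, numbered in emission order so
        the first input item always lands in cluster 0.
    n_clusters_ : int
    """

    def __init__(self, cutoff: float = 0.85, partitioner: str = "pam2",
                 min_split: int = 2, random_state: int = 1):
        self.cutoff = cutoff
        self.partitioner = partitioner
        self.min_split = min_split
        self.random_state = random_state

    def fit(self, X, y=None):
        params = BinaryCutParams(cutoff=self.cutoff,
                                 partitioner=self.partitioner,
                                 min_split=self.min_split,
                                 seed=self.random_state)
        S, _ = _as_similarity_array(X)
        n = S.shape[0]
        if n < 2:
            raise InputError("binary cut needs at least 2 items")
        clusters: list[np.ndarray] = []
        stack: list[np.ndarray] = [np.arange(n)]
        while stack:
            idx = stack.pop()
            sub = S[np.ix_(idx, idx)]
            if _off_diag_mean(sub) >= params.cutoff or len(idx) < params.min_split:
                clusters.append(idx)
                continue
            if params.partitioner == "pam2":
                half = _pam2(sub)
            else:
                half = _kmeans2(sub, params.seed)
            g0, g1 = idx[half == 0], idx[half == 1]
            if len(g0) == 0 or len(g1) == 0:
                clusters.append(idx)  # degenerate split: accept as-is
                continue
            # keep emission order stable by original position
            first, second = (g0, g1) if g0[0] < g1[0] else (g1, g0)
            stack.append(second)
            stack.append(first)
        labels = np.empty(n, dtype=int)
        for c, idx in enumerate(clusters):
            labels[idx] = c
        self.labels_ = labels
        self.n_clusters_ = len(clusters)
        return self


class SimilarityAgglomerative(ClusterMixin, BaseEstimator):
    """Agglomerative clustering on distance 1 - S with silhouette-chosen k.

    With ``n_clusters=None`` the flat cut k is picked to maximise the
    mean silhouette width on the precomputed distance over
    k = 2..min(n-1, 25); ties go to the smallest k.  For n = 2 (where
    no silhouette is defined) the items are split into singletons.
    """

    def __init__(self, linkage: str = "average", n_clusters: int | None = None,
                 max_k: int = MAX_SILHOUETTE_K):
        self.linkage = linkage
        self.n_clusters = n_clusters
        self.max_k = max_k

    def fit(self, X, y=None):
        if self.linkage not in ("average", "complete"):
            raise InputError(f"unsupported linkage {self.linkage!r}")
        S, _ = _as_similarity_array(X)
        n = S.shape[0]
        if n < 2:
            raise InputError("clustering needs at least 2 items")
        if self.n_clusters is not None and not 1 <= self.n_clusters <= n:
            raise InputError(
                f"n_clusters must be in [1, {n}], got {self.n_clusters}"
            )
        D = 1.0 - S
        np.fill_diagonal(D, 0.0)
        D = np.clip((D + D.T) / 2.0, 0.0, None)
        Z = scipy_linkage(squareform(D, checks=False), method=self.linkage)

        if self.n_clusters is not None:
            k = self.n_clusters
            flat = (np.ones(n, dtype=int) if k == 1
                    else fcluster(Z, k, criterion="maxclust"))
        else:
            flat = self._silhouette_cut(D, Z, n)
        # densify to 0-based labels ordered by first occurrence
        order: dict[int, int] = {}
        labels = np.empty(n, dtype=int)
        for i, f in enumerate(flat):
            if f not in order:
                order[f] = len(order)
            labels[i] = order[f]
        self.labels_ = labels
        self.n_clusters_ = len(order)
        return self

    def _silhouette_cut(self, D: np.ndarray, Z, n: int) -> np.ndarray:
        best_score = -np.inf
        best_flat = None
        scores: dict[int, float] = {}
        for k in range(2, min(n - 1, self.max_k) + 1):
            flat = fcluster(Z, k, criterion="maxclust")
            if len(np.unique(flat)) < 2:
                continue
            score = silhouette_score(D, flat, metric="precomputed")
            scores[k] = float(score)
            if score > best_score + _ATOL:  # strict: ties keep smaller k
                best_score = score
                best_flat = flat
        self.silhouette_by_k_ = scores
        if best_flat is None:
            # n == 2 (or all cuts degenerate): split into singletons
            return np.arange(1, n + 1)
        return best_flat


class CombinedClustering(ClusterMixin, BaseEstimator):
    """Binary cut with conditional hierarchical refinement.

    Stage 1 runs binary cut.  Stage 2 re-clusters every stage-1 cluster
    whose within-cluster mean off-diagonal similarity is below
    ``refine_threshold`` or whose size exceeds ``max_cluster_size``,
    using silhouette-cut agglomerative clustering on its submatrix;
    clusters failing neither trigger pass through unchanged and the
    final labels are re-indexed densely.
    """

    def __init__(self, cutoff: float = 0.85, partitioner: str = "pam2",
                 min_split: int = 2, refine_threshold: float = 0.5,
                 max_cluster_size: int = 50, linkage: str = "average",
                 random_state: int = 1):
        self.cutoff = cutoff
        self.partitioner = partitioner
        self.min_split = min_split
        self.refine_threshold = refine_threshold
        self.max_cluster_size = max_cluster_size
        self.linkage = linkage
        self.random_state = random_state

    def fit(self, X, y=None):
        S, _ = _as_similarity_array(X)
        stage1 = BinaryCutClustering(
            cutoff=self.cutoff, partitioner=self.partitioner,
            min_split=self.min_split, random_state=self.random_state,
        ).fit(S)
        labels = np.full(S.shape[0], -1, dtype=int)
        next_label = 0
        n_refined = 0
        for c in range(stage1.n_clusters_):
            idx = np.flatnonzero(stage1.labels_ == c)
            sub = S[np.ix_(idx, idx)]
            within = _off_diag_mean(sub)
            if len(idx) >= 2 and (within < self.refine_threshold
                                  or len(idx) > self.max_cluster_size):
                refine = SimilarityAgglomerative(linkage=self.linkage).fit(sub)
                labels[idx] = refine.labels_ + next_label
                next_label += refine.n_clusters_
                n_refined += 1
            else:
                labels[idx] = next_label
                next_label += 1
        self.labels_ = labels
        self.n_clusters_ = next_label
        self.n_refined_ = n_refined
        return self


# -- functional facade over term ids -----------------------------------------

@dataclass
class ClusterAssignment:
    """term -> 1-based dense cluster labels produced by one method."""

    labels: dict[str, int]
    n_clusters: int
    method: str

    def __post_init__(self) -> None:
        seen = set(self.labels.values())
        if seen != set(range(1, self.n_clusters + 1)):
            raise InputError(
                "cluster indices must be dense 1..n_clusters; got "
                f"{sorted(seen)}"
            )

    def as_array(self, term_ids: Sequence[str]) -> np.ndarray:
        return np.array([self.labels[t] for t in term_ids], dtype=int)

    def members(self, cluster: int) -> list[str]:
        return [t for t, c in self.labels.items() if c == cluster]

    def to_tsv(self) -> str:
        lines = ["term_id\tcluster\tmethod"]
        for t, c in self.labels.items():
            lines.append(f"{t}\t{c}\t{self.method}")
        return "\n".join(lines) + "\n"


def _to_assignment(est, S, method: str) -> ClusterAssignment:
    _, ids = _as_similarity_array(S)
    labels = {t: int(c) + 1 for t, c in zip(ids, est.labels_)}
    return ClusterAssignment(labels=labels, n_clusters=int(est.n_clusters_),
                             method=method)


def binary_cut(S, params: BinaryCutParams | None = None) -> ClusterAssignment:
    params = params or BinaryCutParams()
    est = BinaryCutClustering(cutoff=params.cutoff,
                              partitioner=params.partitioner,
                              min_split=params.min_split,
                              random_state=params.seed).fit(S)
    return _to_assignment(est, S, "binary")


def hierarchical_cluster(S, linkage: str = "average",
                         k: int | None = None) -> ClusterAssignment:
    est = SimilarityAgglomerative(linkage=linkage, n_clusters=k).fit(S)
    return _to_assignment(est, S, "hclust")


def combined_cluster(S, params: BinaryCutParams | None = None,
                     refine_threshold: float = 0.5,
                     max_cluster_size: int = 50,
                     linkage: str = "average") -> ClusterAssignment:
    params = params or BinaryCutParams()
    est = CombinedClustering(cutoff=params.cutoff,
                             partitioner=params.partitioner,
                             min_split=params.min_split,
                             refine_threshold=refine_threshold,
                             max_cluster_size=max_cluster_size,
                             linkage=linkage,
                             random_state=params.seed).fit(S)
    return _to_assignment(est, S, "combined")


# -- separation statistic -----------------------------------------------------

def difference_score(S, assignment) -> float:
    """Mean within-cluster similarity minus mean between-cluster
    similarity over all unordered pairs.

    Singleton clusters contribute no within-pairs; if every cluster is
    a singleton the within-mean is defined as 0.  Requires at least two
    clusters (otherwise no between-pairs exist).
    """
    arr, ids = _as_similarity_array(S)
    if isinstance(assignment, ClusterAssignment):
        missing = [t for t in ids if t not in assignment.labels]
        if missing:
            raise InputError(f"assignment missing terms: {missing[:5]}")
        labels = assignment.as_array(ids)
    else:
        labels = np.asarray(assignment)
        if labels.shape[0] != arr.shape[0]:
            raise InputError("label vector length does not match matrix")
    if len(np.unique(labels)) < 2:
        raise InputError(
            "difference score undefined for fewer than 2 clusters"
        )
    iu = np.triu_indices(arr.shape[0], k=1)
    same = labels[iu[0]] == labels[iu[1]]
    vals = arr[iu]
    within = float(vals[same].mean()) if same.any() else 0.0
    between = float(vals[~same].mean())
    return within - between


# -- method comparison harness ------------------------------------------------

METHODS = ("binary", "hclust", "combined")


def benchmark_methods(
    fixtures: Sequence,
    params: BinaryCutParams | None = None,
    refine_threshold: float = 0.5,
    max_cluster_size: int = 50,
    linkage: str = "average",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run all three methods on each fixture and tabulate separation.

    Returns ``(scores, stats)``: scores has one row per fixture and one
    difference-score column per method; stats holds the paired Wilcoxon
    signed-rank test for every method pair (all-zero difference vectors
    are flagged degenerate with p = 1).  Fixtures failing the matrix
    contract are skipped and logged.
    """
    if len(fixtures) < 2:
        raise InputError("benchmark needs at least 2 fixtures")
    params = params or BinaryCutParams()
    rows = []
    for i, fx in enumerate(fixtures):
        try:
            arr, _ = _as_similarity_array(fx)
        except InputError as exc:
            logger.warning("fixture %d skipped: %s", i, exc)
            continue
        row: dict[str, float] = {"fixture_id": i}
        assignments = {
            "binary": binary_cut(arr, params),
            "hclust": hierarchical_cluster(arr, linkage=linkage),
            "combined": combined_cluster(
                arr, params, refine_threshold=refine_threshold,
                max_cluster_size=max_cluster_size, linkage=linkage),
        }
        for name, asg in assignments.items():
            if asg.n_clusters < 2:
                logger.warning(
                    "fixture %d, method %s yielded a single cluster; "
                    "difference score undefined", i, name)
                row[name] = np.nan
            else:
                row[name] = difference_score(arr, asg)
        rows.append(row)
    scores = pd.DataFrame(rows).set_index("fixture_id")

    stats = []
    for a_idx in range(len(METHODS)):
        for b_idx in range(a_idx + 1, len(METHODS)):
            a, b = METHODS[a_idx], METHODS[b_idx]
            diffs = (scores[a] - scores[b]).dropna().to_numpy()
            if len(diffs) == 0 or np.allclose(diffs, 0.0):
                stats.append({"method_a": a, "method_b": b,
                              "statistic": np.nan, "p_value": 1.0,
                              "degenerate": True})
                continue
            res = wilcoxon(diffs)
            stats.append({"method_a": a, "method_b": b,
                          "statistic": float(res.statistic),
                          "p_value": float(res.pvalue),
                          "degenerate": False})
    return scores, pd.DataFrame(stats)
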