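"""Agglomerative variable clustering by the first-eigenvalue homogeneity criterion.

The homogeneity of a cluster of standardized variables is the largest
eigenvalue lambda1 of its correlation matrix; equivalently the summed
squared Pearson correlations of the member variables with the cluster's
synthetic variable (its first principal component).  Starting from
singletons, the algorithm greedily merges the pair of clusters A, B with
the smallest homogeneity loss

    d(A, B) = lambda1(A) + lambda1(B) - lambda1(A u B) >= 0,

recording a full linkage tree.  Cutting the tree into K blocks undoes the
final K-1 merges.  The drop structure of the merge-height scree suggests a
block count, mirroring the usual by-eye choice on a dendrogram.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClusterMixin

from .io import OmicsMatrix, check_standardized, standardize

__all__ = [
    "LinkageTree",
    "BlockPartition",
    "BlockCountSuggestion",
    "cluster_homogeneity",
    "dissimilarity",
    "agglomerate",
    "cut_tree",
    "suggest_block_count",
    "VariableClustering",
]

#: dissimilarity ties closer than this are broken by member index
TIE_TOL = 1e-12
#: above this cluster size the leading eigenvalue is found by power iteration
DENSE_EIG_LIMIT = 512


def _lambda1(corr_sub: np.ndarray) -> float:
    """Largest eigenvalue of a (sub)correlation matrix.

    Dense symmetric eigendecomposition up to DENSE_EIG_LIMIT variables,
    power iteration (tol 1e-10, <=1000 iterations) beyond that.
    """
    m = corr_sub.shape[0]
    if m == 1:
        return float(corr_sub[0, 0])
    if m <= DENSE_EIG_LIMIT:
        return float(np.linalg.eigvalsh(corr_sub)[-1])
    return _power_lambda1(corr_sub)


def _power_lambda1(corr_sub: np.ndarray, tol: float = 1e-10, max_iter: int = 1000) -> float:
    m = corr_sub.shape[0]
    v = np.full(m, 1.0 / math.sqrt(m))
    lam = 0.0
    for _ in range(max_iter):
        w = corr_sub @ v
        nrm = np.linalg.norm(w)
        if nrm == 0:
            return 0.0
        v_new = w / nrm
        lam_new = float(v_new @ corr_sub @ v_new)
        if abs(lam_new - lam) < tol:
            return lam_new
        v, lam = v_new, lam_new
    return lam


def cluster_homogeneity(columns: np.ndarray) -> tuple[float, np.ndarray]:
    """Homogeneity lambda1 and synthetic-variable scores of a cluster.

    ``columns`` is a standardized n x m matrix.  Returns the largest
    eigenvalue of the m x m correlation matrix together with the first
    principal-component scores, oriented so the variable most correlated
    (in magnitude) with the synthetic variable correlates positively.
    The identity sum_x r(x, scores)^2 == lambda1 holds by construction.
    """
    columns = np.asarray(columns, dtype=float)
    if columns.ndim == 1:
        columns = columns[:, None]
    check_standardized(columns)
    n, m = columns.shape
    corr = columns.T @ columns / (n - 1)
    if m == 1:
        return 1.0, columns[:, 0].copy()
    vals, vecs = np.linalg.eigh(corr)
    lam = float(vals[-1])
    v = vecs[:, -1]
    scores = columns @ v
    # orient: variable with largest |r(x, scores)| correlates positively
    r = corr @ v  # r(x_j, scores) = (X^T X v) / ((n-1) * sd(scores)) up to a positive factor
    j = int(np.argmax(np.abs(r)))
    if r[j] < 0:
        scores = -scores
    return lam, scores


@dataclass
class LinkageTree:
    """Full agglomeration history over the variables of one layer.

    ``merges`` lists p-1 steps in order; each entry is
    ``(id_a, id_b, height, new_id)`` where leaf ids are the original column
    indices 0..p-1 and internal ids continue from p (scipy convention).
    """

    variable_names: list[str]
    merges: list[tuple[int, int, float, int]]
    members: dict[int, tuple[int, ...]] = field(repr=False)

    @property
    def n_variables(self) -> int:
        return len(self.variable_names)

    @property
    def heights(self) -> np.ndarray:
        return np.array([h for _, _, h, _ in self.merges])

    def to_scipy_linkage(self) -> np.ndarray:
        """scipy-style (p-1) x 4 linkage matrix for dendrogram plotting.

        Heights are made non-decreasing by a cumulative max purely for
        display; the raw merge heights are in :attr:`heights`.
        """
        z = np.zeros((len(self.merges), 4))
        running = 0.0
        for i, (a, b, h, new_id) in enumerate(self.merges):
            running = max(running, h)
            z[i] = (a, b, running, len(self.members[new_id]))
        return z

    def clusters_at(self, k: int) -> list[tuple[int, ...]]:
        """Variable-index clusters after undoing the last k-1 merges."""
        p = self.n_variables
        if not 1 <= k <= p:
            raise ValueError(f"K must be in 1..{p}, got {k}")
        active: dict[int, tuple[int, ...]] = {i: (i,) for i in range(p)}
        for a, b, _, new_id in self.merges[: p - k]:
            active[new_id] = tuple(sorted(active.pop(a) + active.pop(b)))
        # deterministic block order: by smallest member index
        return sorted(active.values(), key=lambda t: t[0])


@dataclass
class BlockPartition:
    """A cut of the linkage tree into K disjoint variable blocks."""

    n_blocks: int
    assignment: dict[str, int]  # variable name -> block index 1..K
    homogeneity: list[float]  # lambda1 per block
    scores: pd.DataFrame  # n x K synthetic-variable scores
    blocks: list[list[str]]  # variable names per block

    @property
    def total_homogeneity(self) -> float:
        return float(sum(self.homogeneity))


def dissimilarity(a: np.ndarray, b: np.ndarray, a_ix=None, b_ix=None) -> float:
    """Homogeneity loss of merging two disjoint clusters of standardized columns.

    ``a`` and ``b`` are n x m_a and n x m_b standardized matrices; optional
    index tuples are checked for overlap.
    """
    if a_ix is not None and b_ix is not None and set(a_ix) & set(b_ix):
        raise ValueError("clusters must be disjoint")
    a = np.atleast_2d(np.asarray(a, dtype=float).T).T
    b = np.atleast_2d(np.asarray(b, dtype=float).T).T
    lam_a, _ = cluster_homogeneity(a)
    lam_b, _ = cluster_homogeneity(b)
    lam_ab, _ = cluster_homogeneity(np.hstack([a, b]))
    return lam_a + lam_b - lam_ab


def agglomerate(m: OmicsMatrix) -> LinkageTree:
    """Greedy bottom-up clustering of a layer's variables.

    At each of the p-1 steps the pair of active clusters with minimum
    dissimilarity is merged; ties within TIE_TOL are broken by the pair
    whose smallest member index is lowest, then by the second cluster's
    smallest member index.
    """
    if not m.standardized:
        raise ValueError("agglomerate requires a standardized matrix")
    p = m.n_variables
    if p < 2:
        raise ValueError("need at least 2 variables to cluster")
    X = m.values
    n = m.n_samples
    corr = X.T @ X / (n - 1)

    members: dict[int, tuple[int, ...]] = {i: (i,) for i in range(p)}
    lam: dict[int, float] = {i: 1.0 for i in range(p)}
    active = set(range(p))

    def lam_union(ia: int, ib: int) -> float:
        ix = np.fromiter(members[ia] + members[ib], dtype=int)
        return _lambda1(corr[np.ix_(ix, ix)])

    # pairwise dissimilarity cache keyed by frozen id pair
    d: dict[tuple[int, int], float] = {}
    for i in range(p):
        for j in range(i + 1, p):
            d[(i, j)] = lam[i] + lam[j] - _lambda1(corr[np.ix_((i, j), (i, j))])

    merges: list[tuple[int, int, float, int]] = []
    next_id = p
    for _ in range(p - 1):
        dmin = min(d.values())
        # tie-break among near-minimal pairs by smallest member indices
        best_key = None
        best = None
        for (ia, ib), val in d.items():
            if val <= dmin + TIE_TOL:
                ma, mb = members[ia][0], members[ib][0]
                key = (min(ma, mb), max(ma, mb))
                if best_key is None or key < best_key:
                    best_key, best = key, (ia, ib, val)
        ia, ib, h = best
        new_id = next_id
        next_id += 1
        merged = tuple(sorted(members[ia] + members[ib]))
        members[new_id] = merged
        lam[new_id] = lam[ia] + lam[ib] - h
        active.discard(ia)
        active.discard(ib)
        d = {k: v for k, v in d.items() if ia not in k and ib not in k}
        for other in active:
            key = (min(other, new_id), max(other, new_id))
            d[key] = lam[other] + lam[new_id] - lam_union(other, new_id)
        active.add(new_id)
        merges.append((ia, ib, max(h, 0.0) if abs(h) < TIE_TOL else h, new_id))

    return LinkageTree(variable_names=m.variable_names, merges=merges, members=members)


def cut_tree(tree: LinkageTree, k: int, m: OmicsMatrix) -> BlockPartition:
    """Cut a linkage tree into K blocks and populate homogeneities and scores."""
    if not m.standardized:
        raise ValueError("cut_tree requires the standardized matrix the tree was built on")
    clusters = tree.clusters_at(k)
    X = m.values
    names = tree.variable_names
    assignment: dict[str, int] = {}
    homog: list[float] = []
    blocks: list[list[str]] = []
    score_cols = {}
    for bi, ix in enumerate(clusters, start=1):
        lam, scores = cluster_homogeneity(X[:, list(ix)])
        homog.append(lam)
        block_names = [names[i] for i in ix]
        blocks.append(block_names)
        for nm in block_names:
            assignment[nm] = bi
        score_cols[bi] = scores
    scores_df = pd.DataFrame(score_cols, index=m.data.index)
    return BlockPartition(k, assignment, homog, scores_df, blocks)


class BlockCountSuggestion(NamedTuple):
    """Result of the scree-drop rule for choosing the number of blocks."""

    k: int
    scree: np.ndarray  # height of the K -> K-1 merge, K = 2..k_max
    drops: dict[int, float]  # K -> height(K->K-1 merge) - height(K+1->K merge)
    low_confidence: bool


#: below this best scree drop the block structure is considered flat
FLAT_DROP_THRESHOLD = 0.5


def suggest_block_count(tree: LinkageTree, k_max: int = 20) -> BlockCountSuggestion:
    """Suggest K by the largest consecutive drop on the merge-height scree.

    The scree value at K is the height of the merge that reduces K clusters
    to K-1.  A cut just before a tall merge (a large drop from the K->K-1
    height to the K+1->K height) corresponds to the by-eye dendrogram rule.
    When the best drop is below FLAT_DROP_THRESHOLD the scree is essentially
    flat (no block structure above correlation noise) and the suggestion is
    flagged low-confidence.
    """
    p = tree.n_variables
    if k_max > p:
        raise ValueError(f"k_max must be <= number of variables ({p})")
    heights = tree.heights  # merge i (0-based) reduces p-i clusters to p-i-1

    def height_from(k: int) -> float:
        # height of the merge performed when k clusters remain
        return float(heights[p - k])

    upper = min(k_max, p - 1)
    scree = np.array([height_from(kk) for kk in range(2, min(k_max, p) + 1)])
    drops = {k: height_from(k) - height_from(k + 1) for k in range(2, upper + 1)}
    if not drops:
        return BlockCountSuggestion(2, scree, {}, True)
    best = max(drops.values())
    k = min(kk for kk, v in drops.items() if v >= best - TIE_TOL)
    return BlockCountSuggestion(k, scree, drops, bool(best < FLAT_DROP_THRESHOLD))


class VariableClustering(ClusterMixin, BaseEstimator):
    """Cluster the columns of a data matrix into homogeneous blocks.

    Analogous to :class:`sklearn.cluster.FeatureAgglomeration`, but merges
    maximize the first-eigenvalue homogeneity of each cluster rather than
    minimizing a distance linkage.  Columns are standardized internally.

    Parameters
    ----------
    n_clusters : int or "auto", default="auto"
        Number of blocks; ``"auto"`` applies the scree-drop rule capped at
        ``k_max``.
    k_max : int, default=20
        Upper bound for the automatic block count.

    Attributes
    ----------
    labels_ : ndarray of shape (n_features,)
        Block index (0-based) per column.
    n_clusters_ : int
        Number of blocks actually used.
    tree_ : LinkageTree
    partition_ : BlockPartition
    low_confidence_ : bool
        True when ``n_clusters="auto"`` and the scree was flat.
    """

    def __init__(self, n_clusters: int | str = "auto", k_max: int = 20):
        self.n_clusters = n_clusters
        self.k_max = k_max

    def fit(self, X, y=None):
        m = _as_matrix(X)
        m = m if m.standardized else standardize(m)
        self.tree_ = agglomerate(m)
        if self.n_clusters == "auto":
            sug = suggest_block_count(self.tree_, min(self.k_max, m.n_variables))
            k, self.low_confidence_ = sug.k, sug.low_confidence
            self.suggestion_ = sug
        else:
            k = int(self.n_clusters)
            self.low_confidence_ = False
        self.n_clusters_ = k
        self.partition_ = cut_tree(self.tree_, k, m)
        names = m.variable_names
        self.labels_ = np.array([self.partition_.assignment[nm] - 1 for nm in names])
        self.feature_names_in_ = np.asarray(names, dtype=object)
        return self

    def transform(self, X):
        """Synthetic-variable (first PC) scores per block for new data.

        For the training matrix this equals ``partition_.scores``.
        """
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "partition_")
        m = _as_matrix(X)
        m = m if m.standardized else standardize(m)
        out = {}
        for bi, block in enumerate(self.partition_.blocks, start=1):
            _, scores = cluster_homogeneity(m.data[block].to_numpy())
            out[bi] = scores
        return pd.DataFrame(out, index=m.data.index)


def _as_matrix(X) -> OmicsMatrix:
    if isinstance(X, OmicsMatrix):
        return X
    if isinstance(X, pd.DataFrame):
        return OmicsMatrix(layer_id="X", data=X.astype(float))
    X = np.asarray(X, dtype=float)
    df = pd.DataFrame(X, columns=[f"v{i}" for i in range(X.shape[1])],
                      index=[f"s{i}" for i in range(X.shape[0])])
    return OmicsMatrix(layer_id="X", data=df)
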