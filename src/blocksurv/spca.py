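"""First sparse principal component per variable block.

Each block is summarized by a single sparse PC obtained from the
elastic-net reconstruction objective: minimize over unit vector alpha and
coefficient vector beta

    sum_i || x_i - alpha beta' x_i ||^2 + ridge * ||beta||^2

with the number of nonzero entries of beta fixed at 10% of the block's
variables (round half to even, floor 1) — the "varnum" parameterization of
sparse PCA.  The solver alternates the closed-form alpha update with a
ridge regression of ``X alpha`` on ``X`` whose solution is hard-thresholded
to the top-k magnitudes and re-solved on that support, starting from the
block's first eigenvector.  The component is the unit-norm beta; its scores
are ``X beta / ||beta||``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from decimal import ROUND_HALF_EVEN, Decimal

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .io import OmicsMatrix, check_standardized, standardize
from .varclust import BlockPartition

__all__ = [
    "SparseComponent",
    "nonzero_count",
    "first_sparse_pc",
    "orient_component",
    "extract_all",
    "BlockSparsePCA",
]

DEFAULT_FRACTION = 0.10
DEFAULT_RIDGE = 1e-6


@dataclass
class SparseComponent:
    """First sparse PC of one block.

    ``loadings`` is the unit-norm coefficient vector over the block's
    variables with exactly ``k`` nonzeros; ``scores`` is the n-vector of
    component values (block matrix times loadings).
    """

    layer_id: str
    block_index: int
    label: str  # layer prefix + block index, e.g. "D4"
    variable_names: list[str]
    loadings: np.ndarray
    scores: pd.Series
    k: int
    ridge: float
    converged: bool = True

    @property
    def support(self) -> list[str]:
        return [nm for nm, b in zip(self.variable_names, self.loadings) if b != 0]

    @property
    def n_block_variables(self) -> int:
        return len(self.variable_names)

    def loading_of(self, name: str) -> float:
        return float(self.loadings[self.variable_names.index(name)])


def nonzero_count(p_block: int, fraction: float = DEFAULT_FRACTION) -> int:
    """Number of nonzero loadings for a block of ``p_block`` variables.

    Banker's rounding (half to even) of ``fraction * p_block``, floored at
    one so every block keeps a representative variable.  Computed in
    decimal arithmetic: binary floats would round 0.1 * 65 up.
    """
    if p_block < 1:
        raise ValueError("block must contain at least one variable")
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    k = int((Decimal(str(fraction)) * p_block).to_integral_value(rounding=ROUND_HALF_EVEN))
    return max(1, min(k, p_block))


def _solve_ridge_support(S: np.ndarray, support: np.ndarray, ridge: float) -> np.ndarray:
    """Fixed point of the ridge alternation restricted to a support.

    Solving the rank-1 reconstruction subproblem on the support columns
    alone, the alpha/beta alternation converges to the leading eigenvector
    of the support submatrix scaled by lam1/(lam1 + ridge); solving to
    that fixed point directly keeps out-of-support correlations from
    leaking into the restricted direction.  Oriented (largest-|entry|
    positive) so iterates are comparable across iterations.
    """
    beta = np.zeros(S.shape[0])
    sub = S[np.ix_(support, support)]
    vals, vecs = np.linalg.eigh(sub)
    v = vecs[:, -1]
    j = int(np.argmax(np.abs(v)))
    if v[j] < 0:
        v = -v
    beta[support] = v * (vals[-1] / (vals[-1] + ridge))
    return beta


def first_sparse_pc(
    block: np.ndarray,
    k: int,
    ridge: float = DEFAULT_RIDGE,
    tol: float = 1e-8,
    max_iter: int = 500,
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Alternating solver for the k-sparse first component of one block.

    Parameters
    ----------
    block : ndarray of shape (n, p_block)
        Standardized columns of one block.
    k : int
        Exact nonzero count of the loading vector.
    ridge : float
        L2 penalty of the elastic-net objective (kept small; the sparsity
        is driven by the count constraint, not the penalty).

    Returns
    -------
    loadings : unit-norm p_block-vector with k nonzeros
    scores : n-vector, block @ loadings
    converged : bool
    """
    X = np.asarray(block, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    check_standardized(X)
    n, p = X.shape
    if not 1 <= k <= p:
        raise ValueError(f"k must be in 1..{p}, got {k}")
    S = X.T @ X / (n - 1)  # correlation matrix

    vals, vecs = np.linalg.eigh(S)
    beta = vecs[:, -1].copy()
    support = _top_k_support(beta, k)
    beta = _solve_ridge_support(S, support, ridge)

    converged = False
    for _ in range(max_iter):
        alpha = _unit(S @ beta)
        beta_full = np.linalg.solve(S + ridge * np.eye(p), S @ alpha)
        new_support = _top_k_support(beta_full, k)
        new_beta = _solve_ridge_support(S, new_support, ridge)
        same = np.array_equal(np.sort(new_support), np.sort(support))
        delta = np.max(np.abs(_unit(new_beta) - _unit(beta))) if same else np.inf
        support, beta = new_support, new_beta
        if same and delta < tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"sparse PC did not converge in {max_iter} iterations; returning last iterate",
            RuntimeWarning,
        )
    support = _swap_refine(S, support)
    support = _enumerate_if_small(S, support)
    beta = _solve_ridge_support(S, support, ridge)
    loadings = _unit(beta)
    scores = X @ loadings
    return loadings, scores, converged


#: supports are enumerated exactly when C(p, k) does not exceed this
ENUMERATION_LIMIT = 20_000


def _enumerate_if_small(S: np.ndarray, support: np.ndarray) -> np.ndarray:
    """Exact best support by enumeration when the search space is small.

    The alternation plus local swaps can still settle on a sub-optimal
    support (sparse PCA is a combinatorial problem); for blocks where
    C(p, k) <= ENUMERATION_LIMIT every support is scored by its leading
    eigenvalue in one batched eigendecomposition, certifying the result.
    """
    import itertools
    from math import comb

    p, k = S.shape[0], support.size
    if k >= p or comb(p, k) > ENUMERATION_LIMIT:
        return support
    combos = np.fromiter(
        itertools.chain.from_iterable(itertools.combinations(range(p), k)),
        dtype=int,
    ).reshape(-1, k)
    subs = S[combos[:, :, None], combos[:, None, :]]
    vals = np.linalg.eigvalsh(subs)[:, -1]
    best = int(np.argmax(vals))
    if vals[best] > _support_value(S, support) + 1e-10:
        return combos[best]
    return support


def _support_value(S: np.ndarray, support: np.ndarray) -> float:
    return float(np.linalg.eigvalsh(S[np.ix_(support, support)])[-1])


def _swap_refine(S: np.ndarray, support: np.ndarray, max_passes: int = 100) -> np.ndarray:
    """Deterministic local search over supports.

    The alternating iteration can settle on a support whose constrained
    component explains less variance than another support of the same
    size.  Repeatedly apply the best single swap (one variable out, one
    in) that increases the support's leading eigenvalue, until no swap
    improves; ties are impossible to matter since only strict
    improvements are taken, scanning swaps in index order.
    """
    p = S.shape[0]
    support = np.sort(np.asarray(support))
    k = support.size
    if k == p:
        return support
    current = _support_value(S, support)
    for _ in range(max_passes):
        best_gain = 1e-10
        best_support = None
        outside = np.setdiff1d(np.arange(p), support)
        for i in range(k):
            for j in outside:
                cand = support.copy()
                cand[i] = j
                cand.sort()
                val = _support_value(S, cand)
                if val - current > best_gain:
                    best_gain = val - current
                    best_support = cand
        if best_support is None:
            return support
        support = best_support
        current += best_gain
    return support


def _unit(v: np.ndarray) -> np.ndarray:
    nrm = np.linalg.norm(v)
    if nrm == 0:
        raise ValueError("degenerate zero vector in sparse PC iteration")
    return v / nrm


def _top_k_support(beta: np.ndarray, k: int) -> np.ndarray:
    """Indices of the k largest |beta|, ties broken by lower index."""
    order = np.lexsort((np.arange(beta.size), -np.abs(beta)))
    return np.sort(order[:k])


def orient_component(c: SparseComponent) -> SparseComponent:
    """Make the largest-magnitude loading positive (sign convention)."""
    j = int(np.argmax(np.abs(c.loadings)))
    if c.loadings[j] < 0:
        return replace(c, loadings=-c.loadings, scores=-c.scores)
    return c


def extract_all(
    partition: BlockPartition,
    m: OmicsMatrix,
    fraction: float = DEFAULT_FRACTION,
    ridge: float = DEFAULT_RIDGE,
) -> list[SparseComponent]:
    """One oriented sparse component per block of a layer.

    Labels are layer-prefixed and block-ordered (``D1``, ``D2``, ...).
    """
    if partition.n_blocks == 0 or not partition.blocks:
        raise ValueError("empty partition")
    missing = set(partition.assignment) - set(m.variable_names)
    if missing:
        raise ValueError(f"partition refers to variables absent from layer: {sorted(missing)[:5]}")
    components = []
    for bi, block_names in enumerate(partition.blocks, start=1):
        sub = m.data[block_names].to_numpy()
        k = nonzero_count(len(block_names), fraction)
        loadings, scores, converged = first_sparse_pc(sub, k, ridge=ridge)
        c = SparseComponent(
            layer_id=m.layer_id,
            block_index=bi,
            label=f"{m.layer_id}{bi}",
            variable_names=list(block_names),
            loadings=loadings,
            scores=pd.Series(scores, index=m.data.index, name=f"{m.layer_id}{bi}"),
            k=k,
            ridge=ridge,
            converged=converged,
        )
        components.append(orient_component(c))
    return components


def loadings_table(components: list[SparseComponent]) -> pd.DataFrame:
    """Long-format table of nonzero loadings (component, variable, loading)."""
    rows = [
        (c.label, nm, float(b))
        for c in components
        for nm, b in zip(c.variable_names, c.loadings)
        if b != 0
    ]
    return pd.DataFrame(rows, columns=["component", "variable", "loading"])


class BlockSparsePCA(TransformerMixin, BaseEstimator):
    """Per-block sparse PCA transformer.

    Given a block assignment over the input columns, fits one k-sparse
    first component per block (k = ``fraction`` of the block size, half to
    even, floor 1) and transforms a matrix to the component scores.

    Parameters
    ----------
    blocks : mapping, array-like or None
        Variable name -> block label, or an array of block labels aligned
        with the columns.  ``None`` treats all columns as a single block.
    fraction : float, default=0.10
        Nonzero-loading fraction per block.
    ridge : float, default=1e-6
        Elastic-net L2 penalty.
    layer_id : str, default="X"
        Prefix for component labels.

    Attributes
    ----------
    components_ : list of SparseComponent
    feature_names_in_ : ndarray
    """

    def __init__(self, blocks=None, fraction: float = DEFAULT_FRACTION,
                 ridge: float = DEFAULT_RIDGE, layer_id: str = "X"):
        self.blocks = blocks
        self.fraction = fraction
        self.ridge = ridge
        self.layer_id = layer_id

    def fit(self, X, y=None):
        m = _as_layer(X, self.layer_id)
        m = m if m.standardized else standardize(m)
        names = m.variable_names
        if self.blocks is None:
            groups = {1: list(names)}
        elif isinstance(self.blocks, dict):
            groups = {}
            for nm in names:
                groups.setdefault(self.blocks[nm], []).append(nm)
        else:
            labels = np.asarray(self.blocks)
            if labels.size != len(names):
                raise ValueError("blocks array length must match number of columns")
            groups = {}
            for nm, lb in zip(names, labels):
                groups.setdefault(lb, []).append(nm)
        self.components_ = []
        for bi, key in enumerate(sorted(groups, key=str), start=1):
            block_names = groups[key]
            sub = m.data[block_names].to_numpy()
            k = nonzero_count(len(block_names), self.fraction)
            loadings, scores, converged = first_sparse_pc(sub, k, ridge=self.ridge)
            c = SparseComponent(
                layer_id=m.layer_id, block_index=bi, label=f"{m.layer_id}{bi}",
                variable_names=list(block_names), loadings=loadings,
                scores=pd.Series(scores, index=m.data.index, name=f"{m.layer_id}{bi}"),
                k=k, ridge=self.ridge, converged=converged,
            )
            self.components_.append(orient_component(c))
        self.feature_names_in_ = np.asarray(names, dtype=object)
        return self

    def transform(self, X):
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "components_")
        m = _as_layer(X, self.layer_id)
        m = m if m.standardized else standardize(m)
        out = {}
        for c in self.components_:
            out[c.label] = m.data[c.variable_names].to_numpy() @ c.loadings
        return pd.DataFrame(out, index=m.data.index)

    def get_feature_names_out(self, input_features=None):
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "components_")
        return np.asarray([c.label for c in self.components_], dtype=object)


def _as_layer(X, layer_id: str) -> OmicsMatrix:
    if isinstance(X, OmicsMatrix):
        return X
    if isinstance(X, pd.DataFrame):
        return OmicsMatrix(layer_id=layer_id, data=X.astype(float))
    X = np.asarray(X, dtype=float)
    df = pd.DataFrame(X, columns=[f"v{i}" for i in range(X.shape[1])],
                      index=[f"s{i}" for i in range(X.shape[0])])
    return OmicsMatrix(layer_id=layer_id, data=df)
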