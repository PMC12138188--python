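"""Community coevolution model (CCM) core.

The CCM is a continuous-time Markov chain over the joint presence/absence
state of ``n`` binary features.  A system state is a vector
``x = (x_1, ..., x_n)`` with ``x_k = -1`` (absent) or ``+1`` (present).
From state ``x`` the chain can flip exactly one feature at a time; the
instantaneous rate of flipping feature ``k`` is log-linear in the state:

    log tau_k(x) = alpha_k - beta_kk * x_k - sum_{h != k} beta_hk * x_k * x_h

``alpha_k`` is the intrinsic log-rate of change for feature ``k``,
``beta_kk`` is half the difference between the gain and loss log-rates
(positive values favour presence), and ``beta_hk`` couples features ``h``
and ``k``: positive values make concordant states sticky (coevolution),
negative values make them repulsive.

States are indexed by the bit convention ``b_k = (x_k + 1) / 2`` with
feature 0 in the least-significant bit, so the all-absent state is index 0
and the all-present state is index ``2**n - 1``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
from scipy.linalg import expm

from .errors import (
    InvalidBranchLengthError,
    InvalidStateError,
    MissingTipError,
    StateSpaceTooLargeError,
    TreeShapeError,
)

#: Largest feature count the dense 2**n state space is built for.
MAX_FEATURES = 10

#: Row-stochasticity tolerance for transition matrices.
ROW_SUM_TOL = 1e-10


def _as_state_array(states: Iterable[int]) -> np.ndarray:
    arr = np.asarray(list(states), dtype=float)
    if arr.ndim != 1 or arr.size == 0:
        raise InvalidStateError("state vector must be a non-empty 1-D sequence")
    if not np.all(np.isin(arr, (-1.0, 1.0))):
        raise InvalidStateError(
            f"state entries must be -1 or +1, got {arr.tolist()}"
        )
    return arr


def state_index(states: Iterable[int]) -> int:
    """Map a +/-1 state vector to its row index in the rate matrix.

    Bit convention: ``b_k = (x_k + 1)/2`` and feature 0 is the
    least-significant bit, so ``(-1, -1) -> 0`` and ``(+1, +1) -> 3``.
    """
    arr = _as_state_array(states)
    bits = ((arr + 1) / 2).astype(int)
    return int(np.sum(bits << np.arange(bits.size)))


def state_space(n: int) -> np.ndarray:
    """All ``2**n`` states as a ``(2**n, n)`` array of -1/+1, in index order."""
    if n < 1:
        raise StateSpaceTooLargeError("need at least one feature")
    if n > MAX_FEATURES:
        raise StateSpaceTooLargeError(
            f"n={n} exceeds the {MAX_FEATURES}-feature state-space guard"
        )
    idx = np.arange(2**n)[:, None]
    bits = (idx >> np.arange(n)[None, :]) & 1
    return 2.0 * bits - 1.0


@dataclass(frozen=True)
class CCMParameters:
    """Parameters of an n-feature CCM.

    Parameters
    ----------
    alpha
        Length-n intrinsic log-rates, one per feature.
    beta_diag
        Length-n values ``beta_kk``; half the gain/loss log-rate difference.
    beta_inter
        Interaction coefficients for the ``n*(n-1)/2`` unordered feature
        pairs, in lexicographic pair order ``(0,1), (0,2), ..., (n-2,n-1)``.
        A single value serves both orderings of a pair.
    """

    alpha: tuple[float, ...]
    beta_diag: tuple[float, ...]
    beta_inter: tuple[float, ...] = field(default=())

    def __post_init__(self) -> None:
        n = len(self.alpha)
        object.__setattr__(self, "alpha", tuple(float(a) for a in self.alpha))
        object.__setattr__(
            self, "beta_diag", tuple(float(b) for b in self.beta_diag)
        )
        object.__setattr__(
            self, "beta_inter", tuple(float(b) for b in self.beta_inter)
        )
        if len(self.beta_diag) != n:
            raise ValueError("alpha and beta_diag must have equal length")
        if len(self.beta_inter) != n * (n - 1) // 2:
            raise ValueError(
                f"beta_inter needs n*(n-1)/2 = {n * (n - 1) // 2} entries, "
                f"got {len(self.beta_inter)}"
            )

    @property
    def n_features(self) -> int:
        return len(self.alpha)

    def interaction_matrix(self) -> np.ndarray:
        """Symmetric ``(n, n)`` matrix of beta_hk with a zero diagonal."""
        n = self.n_features
        B = np.zeros((n, n))
        pos = 0
        for h in range(n):
            for k in range(h + 1, n):
                B[h, k] = B[k, h] = self.beta_inter[pos]
                pos += 1
        return B

    def interaction(self, h: int, k: int) -> float:
        if h == k:
            raise ValueError("interaction requires two distinct features")
        return float(self.interaction_matrix()[h, k])

    @classmethod
    def for_pair(
        cls,
        alpha1: float,
        alpha2: float,
        beta11: float,
        beta22: float,
        beta12: float,
    ) -> "CCMParameters":
        """Convenience constructor for the two-feature model (5 parameters)."""
        return cls((alpha1, alpha2), (beta11, beta22), (beta12,))


def transition_rate(states: Iterable[int], k: int, params: CCMParameters) -> float:
    """Instantaneous rate of flipping feature ``k`` from the given state."""
    x = _as_state_array(states)
    n = x.size
    if not 0 <= k < n:
        raise IndexError(f"feature index {k} out of range for n={n}")
    if params.n_features != n:
        raise ValueError("parameter dimension does not match the state vector")
    B = params.interaction_matrix()
    exponent = (
        params.alpha[k]
        - params.beta_diag[k] * x[k]
        - x[k] * float(B[:, k] @ x)
    )
    return float(np.exp(exponent))


def build_rate_matrix(params: CCMParameters, n: int | None = None) -> np.ndarray:
    """Dense ``(2**n, 2**n)`` CTMC generator of the CCM.

    Entry ``(i, j)`` is the flip rate of the single feature in which states
    ``i`` and ``j`` differ; states differing in more than one feature get 0,
    and the diagonal makes every row sum to zero.
    """
    if n is None:
        n = params.n_features
    if params.n_features != n:
        raise ValueError("parameter dimension does not match n")
    X = state_space(n)  # raises the guard error for n > MAX_FEATURES
    S = X.shape[0]
    B = params.interaction_matrix()
    alpha = np.asarray(params.alpha)
    beta_diag = np.asarray(params.beta_diag)

    Q = np.zeros((S, S))
    idx = np.arange(S)
    for k in range(n):
        exponent = alpha[k] - beta_diag[k] * X[:, k] - X[:, k] * (X @ B[:, k])
        Q[idx, idx ^ (1 << k)] = np.exp(exponent)
    Q[idx, idx] = -Q.sum(axis=1)
    return Q


def transition_probabilities(Q: np.ndarray, t: float) -> np.ndarray:
    """Transition matrix ``exp(Q t)``; row-stochastic within ``ROW_SUM_TOL``."""
    if t < 0:
        raise InvalidBranchLengthError(f"branch length must be >= 0, got {t}")
    if t == 0:
        return np.eye(Q.shape[0])
    P = expm(Q * t)
    np.clip(P, 0.0, None, out=P)
    P /= P.sum(axis=1, keepdims=True)
    return P


def transition_stack(Q: np.ndarray, ts: np.ndarray) -> np.ndarray:
    """``exp(Q t)`` for a batch of branch lengths, shape ``(len(ts), S, S)``.

    Uses a single eigendecomposition of ``Q`` when it is well conditioned,
    which turns each branch into two small matrix products; falls back to a
    per-branch Pade exponential otherwise.
    """
    ts = np.asarray(ts, dtype=float)
    if np.any(ts < 0):
        raise InvalidBranchLengthError("branch lengths must be >= 0")
    S = Q.shape[0]
    P = None
    try:
        with np.errstate(over="ignore", invalid="ignore"):
            lam, V = np.linalg.eig(Q)
            Vinv = np.linalg.inv(V)
            if np.linalg.cond(V) < 1e8:
                E = np.exp(np.multiply.outer(ts, lam))  # (T, S)
                P = np.einsum("ij,tj,jk->tik", V, E, Vinv).real
                err = np.max(np.abs(P.sum(axis=2) - 1.0))
                if not np.isfinite(err) or err > 1e-9 or P.min() < -1e-9:
                    P = None
    except np.linalg.LinAlgError:
        P = None
    if P is None:
        P = np.stack([expm(Q * t) for t in ts]) if len(ts) else np.empty((0, S, S))
    np.clip(P, 0.0, None, out=P)
    P /= P.sum(axis=2, keepdims=True)
    P[ts == 0] = np.eye(S)
    return P


@dataclass(frozen=True)
class TreeIndex:
    """Flattened post-order view of a rooted binary tree for pruning.

    Nodes are numbered so leaves come first (``0 .. n_leaves-1`` in
    ``leaf_labels`` order) followed by internal nodes in post-order; the
    root is the last node.  Every non-root node carries the length of the
    edge to its parent in ``branch_lengths``.
    """

    leaf_labels: tuple[str, ...]
    left_child: np.ndarray  # (n_internal,) node ids
    right_child: np.ndarray  # (n_internal,)
    branch_lengths: np.ndarray  # (n_nodes,), root entry unused (0)

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_labels)

    @property
    def n_nodes(self) -> int:
        return self.branch_lengths.size

    @property
    def total_length(self) -> float:
        return float(self.branch_lengths[:-1].sum())

    @classmethod
    def from_tree(cls, tree: dendropy.Tree) -> "TreeIndex":
        leaves = [lf for lf in tree.leaf_node_iter()]
        labels = tuple(lf.taxon.label if lf.taxon else lf.label for lf in leaves)
        ids: dict[int, int] = {id(lf): i for i, lf in enumerate(leaves)}
        left, right, blen = [], [], [0.0] * len(leaves)
        for node in tree.postorder_node_iter():
            if node.is_leaf():
                continue
            children = node.child_nodes()
            if len(children) != 2:
                raise TreeShapeError(
                    f"pruning requires a strictly binary tree; a node has "
                    f"{len(children)} children"
                )
            ids[id(node)] = len(blen)
            blen.append(0.0)
            left.append(ids[id(children[0])])
            right.append(ids[id(children[1])])
        for node in tree.postorder_node_iter():
            if node is tree.seed_node:
                continue
            length = node.edge.length
            if length is None:
                raise InvalidBranchLengthError("a non-root edge has no length")
            if length < 0:
                raise InvalidBranchLengthError(
                    f"negative branch length {length}"
                )
            blen[ids[id(node)]] = float(length)
        return cls(
            leaf_labels=labels,
            left_child=np.asarray(left, dtype=np.intp),
            right_child=np.asarray(right, dtype=np.intp),
            branch_lengths=np.asarray(blen, dtype=float),
        )


def _tip_state_indices(
    index: TreeIndex, tips: Mapping[str, Sequence[int]], n: int
) -> np.ndarray:
    out = np.empty(index.n_leaves, dtype=np.intp)
    for i, label in enumerate(index.leaf_labels):
        if label not in tips:
            raise MissingTipError(f"leaf {label!r} has no observed state")
        sv = _as_state_array(tips[label])
        if sv.size != n:
            raise InvalidStateError(
                f"tip state for {label!r} has length {sv.size}, expected {n}"
            )
        out[i] = state_index(sv)
    return out


def pruning_log_likelihood(
    index: TreeIndex,
    tip_indices: np.ndarray,
    Q: np.ndarray,
    root_dist: np.ndarray | None = None,
) -> float:
    """Felsenstein pruning on a pre-flattened tree with tip state indices.

    Partial likelihood vectors are renormalised at each internal node and the
    log of the scaling factors accumulated, so the result stays finite on
    large trees.
    """
    S = Q.shape[0]
    if root_dist is None:
        root_dist = np.full(S, 1.0 / S)
    else:
        root_dist = np.asarray(root_dist, dtype=float)
        if root_dist.shape != (S,) or not np.isclose(root_dist.sum(), 1.0):
            raise ValueError("root_dist must be a length-2**n probability vector")

    if index.left_child.size == 0:  # a bare single-leaf tree
        return float(np.log(root_dist[tip_indices[0]]))
    P = transition_stack(Q, index.branch_lengths)
    n_leaves = index.n_leaves
    # messages[v] = P_v @ partial_v, the contribution of node v to its parent;
    # for a leaf with observed state j this is just column j of P_v.
    messages = np.empty((index.n_nodes, S))
    messages[:n_leaves] = P[np.arange(n_leaves), :, tip_indices]

    log_scale = 0.0
    partial = None
    for pos in range(index.left_child.size):
        v = n_leaves + pos
        w = messages[index.left_child[pos]] * messages[index.right_child[pos]]
        s = w.sum()
        if s <= 0:
            return -np.inf
        partial = w / s
        log_scale += np.log(s)
        messages[v] = P[v] @ partial
    root_mass = float(root_dist @ partial)
    if root_mass <= 0:
        return -np.inf
    return float(np.log(root_mass) + log_scale)


def tree_log_likelihood(
    tree: dendropy.Tree,
    tips: Mapping[str, Sequence[int]],
    params: CCMParameters,
    root_dist: np.ndarray | None = None,
) -> float:
    """Log-likelihood of observed leaf states under the CCM.

    Parameters
    ----------
    tree
        Rooted, strictly binary tree with branch lengths.
    tips
        Mapping from leaf label to a -1/+1 state vector of length n.
    params
        CCM parameters for n features.
    root_dist
        Probability vector over the ``2**n`` states at the root; uniform by
        default.
    """
    index = TreeIndex.from_tree(tree)
    n = params.n_features
    tip_idx = _tip_state_indices(index, tips, n)
    Q = build_rate_matrix(params)
    return pruning_log_likelihood(index, tip_idx, Q, root_dist)


def stationary_distribution(Q: np.ndarray) -> np.ndarray:
    """Stationary probability vector of the CTMC generator ``Q``."""
    S = Q.shape[0]
    A = np.vstack([Q.T, np.ones(S)])
    b = np.zeros(S + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(A, b, rcond=None)
    pi = np.clip(pi, 0.0, None)
    return pi / pi.sum()
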