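"""Forward simulation of the CCM along a phylogeny.

Profiles are evolved exactly: the root state is drawn from the model's
root distribution (uniform by default) and each child state is drawn from
the row of the branch's transition matrix ``exp(Q t)`` indexed by the
parent state.  Because the state space is tiny (at most ``2**10``), the
exact matrix exponential is used for every branch rather than event-level
simulation, which is correct for arbitrary branch lengths.

Trees are sampled coalescent-style: lineages are merged uniformly at
random two at a time, and every edge receives an independent exponential
length, deterministic under a seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import dendropy
import numpy as np
import pandas as pd

from .io import FeatureTable
from .model import (
    CCMParameters,
    TreeIndex,
    build_rate_matrix,
    state_index,
    state_space,
    transition_stack,
)
from .trees import read_newick


def sample_tree(
    leaves: int,
    seed: int,
    mean_branch_length: float = 0.3,
    label_prefix: str = "G",
) -> dendropy.Tree:
    """Random rooted binary tree over ``leaves`` labelled genomes.

    Topology: repeated uniform joins of two random lineages.  Branch
    lengths: i.i.d. exponential with the given mean.  Identical seeds give
    identical Newick output.
    """
    if leaves < 2:
        raise ValueError("need at least two leaves")
    rng = np.random.default_rng(seed)
    width = len(str(leaves))
    lineages = [
        f"{label_prefix}{i + 1:0{width}d}" for i in range(leaves)
    ]  # Newick fragments
    lengths = rng.exponential(mean_branch_length, size=2 * leaves - 2)
    pos = 0
    while len(lineages) > 1:
        i, j = sorted(rng.choice(len(lineages), size=2, replace=False))
        right = lineages.pop(j)
        left = lineages.pop(i)
        merged = (
            f"({left}:{lengths[pos]:.12g},{right}:{lengths[pos + 1]:.12g})"
        )
        pos += 2
        lineages.append(merged)
    return read_newick(lineages[0] + ";")


@dataclass(frozen=True)
class SimulationScenario:
    """A reproducible simulation setup.

    Either ``tree`` or ``leaves`` must be given; with ``leaves`` a fresh
    tree is sampled per scenario (shared across replicates) from the seed.
    """

    params: CCMParameters
    seed: int
    tree: dendropy.Tree | None = None
    leaves: int | None = None
    mean_branch_length: float = 0.3
    root_state: Sequence[int] | None = None  # -1/+1 vector; None = sampled
    replicates: int = 1

    def resolve_tree(self) -> dendropy.Tree:
        if self.tree is not None:
            return self.tree
        if self.leaves is None:
            raise ValueError("scenario needs a tree or a leaf count")
        return sample_tree(self.leaves, self.seed, self.mean_branch_length)


def _feature_names(n: int) -> list[str]:
    return [f"F{k + 1}" for k in range(n)]


def simulate_on_index(
    index: TreeIndex,
    params: CCMParameters,
    rng: np.random.Generator,
    root_state: Sequence[int] | None = None,
    root_dist: np.ndarray | None = None,
) -> pd.DataFrame:
    """One replicate of leaf 0/1 profiles on a pre-flattened tree."""
    n = params.n_features
    Q = build_rate_matrix(params)
    S = Q.shape[0]
    P = transition_stack(Q, index.branch_lengths)
    if root_state is not None:
        root_idx = state_index(root_state)
    else:
        dist = np.full(S, 1.0 / S) if root_dist is None else np.asarray(root_dist)
        root_idx = int(rng.choice(S, p=dist))

    # Walk the flattened post-order structure in reverse (pre-order).
    states = np.empty(index.n_nodes, dtype=np.intp)
    states[-1] = root_idx
    for pos in range(index.left_child.size - 1, -1, -1):
        v = index.n_leaves + pos
        for child in (index.left_child[pos], index.right_child[pos]):
            states[child] = int(rng.choice(S, p=P[child, states[v]]))

    X = state_space(n)
    leaf_bits = ((X[states[: index.n_leaves]] + 1) / 2).astype(np.int8)
    return pd.DataFrame(
        leaf_bits, index=list(index.leaf_labels), columns=_feature_names(n)
    )


def simulate_profiles(scenario: SimulationScenario) -> list[FeatureTable]:
    """All replicates of a scenario as validated feature tables."""
    tree = scenario.resolve_tree()
    index = TreeIndex.from_tree(tree)
    rng = np.random.default_rng(scenario.seed)
    return [
        FeatureTable(
            simulate_on_index(index, scenario.params, rng, scenario.root_state)
        )
        for _ in range(scenario.replicates)
    ]


def simulate_pair_table(
    tree: dendropy.Tree | TreeIndex,
    params: CCMParameters,
    seed: int,
    root_state: Sequence[int] | None = None,
) -> pd.DataFrame:
    """Convenience: one replicate of a (usually two-feature) profile table."""
    index = tree if isinstance(tree, TreeIndex) else TreeIndex.from_tree(tree)
    rng = np.random.default_rng(seed)
    return simulate_on_index(index, params, rng, root_state)


def simulate_fixture(
    leaves: int,
    n_features: int,
    seed: int,
    beta12: float = 0.0,
    alpha: float = 0.0,
    mean_branch_length: float = 0.3,
) -> tuple[FeatureTable, dendropy.Tree]:
    """A ready-to-run (feature table, tree) pair for end-to-end runs.

    Features are simulated in independent coupled pairs: features ``2j-1``
    and ``2j`` evolve under a shared interaction coefficient ``beta12``
    while distinct pairs are independent, so the table can have any width
    without leaving the pairwise model.  An odd trailing feature evolves
    alone.  Names carry a ``pair<j>_`` prefix so prefix-based subsetting
    can be exercised.
    """
    tree = sample_tree(leaves, seed, mean_branch_length)
    index = TreeIndex.from_tree(tree)
    rng = np.random.default_rng(seed + 1)
    columns = {}
    j = 0
    while len(columns) < n_features:
        j += 1
        remaining = n_features - len(columns)
        if remaining >= 2:
            params = CCMParameters.for_pair(alpha, alpha, 0.0, 0.0, beta12)
            table = simulate_on_index(index, params, rng)
            columns[f"pair{j}_a"] = table.iloc[:, 0]
            columns[f"pair{j}_b"] = table.iloc[:, 1]
        else:
            params = CCMParameters((alpha,), (0.0,), ())
            table = simulate_on_index(index, params, rng)
            columns[f"solo{j}"] = table.iloc[:, 0]
    frame = pd.DataFrame(columns, index=list(index.leaf_labels))
    return FeatureTable(frame), tree
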