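"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

import phyloccm as pc
from phyloccm.model import build_rate_matrix, transition_probabilities


def enumeration_log_likelihood(tree, tips, params, root_dist=None):
    """Brute-force tree likelihood: explicit sum over every assignment of
    states to internal nodes.  Exponential in tree size; the independent
    oracle for the pruning recursion on tiny trees."""
    Q = build_rate_matrix(params)
    S = Q.shape[0]
    if root_dist is None:
        root_dist = np.full(S, 1.0 / S)
    nodes = list(tree.postorder_node_iter())
    internals = [n for n in nodes if not n.is_leaf()]
    P = {
        id(n): transition_probabilities(Q, n.edge.length)
        for n in nodes
        if n is not tree.seed_node
    }
    leaf_state = {
        id(n): pc.state_index(tips[n.taxon.label]) for n in nodes if n.is_leaf()
    }
    total = 0.0
    root = tree.seed_node
    for assignment in itertools.product(range(S), repeat=len(internals)):
        states = dict(leaf_state)
        for node, s in zip(internals, assignment):
            states[id(node)] = s
        prob = root_dist[states[id(root)]]
        for n in nodes:
            if n is root:
                continue
            prob *= P[id(n)][states[id(n.parent_node)], states[id(n)]]
        total += prob
    return float(np.log(total))


def random_pair_params(rng, scale=1.0):
    """Random 2-feature CCM parameters for property checks."""
    a1, a2 = rng.normal(0, scale, 2)
    b11, b22 = rng.normal(0, scale / 2, 2)
    b12 = rng.normal(0, scale / 2)
    return pc.CCMParameters.for_pair(a1, a2, b11, b22, b12)


def collect_fits(
    leaves, beta12, n_fits, seed_base, alpha=0.0, mean_branch_length=0.3
):
    """Seeded replicate fits: fresh tree + profiles per replicate, skipping
    draws where a column is constant (those cannot be fit by contract)."""
    fits = []
    truth = []
    offset = 0
    params = pc.CCMParameters.for_pair(alpha, alpha, 0.0, 0.0, beta12)
    while len(fits) < n_fits:
        seed = seed_base + offset
        offset += 1
        if offset > 20 * n_fits:
            raise RuntimeError("too many degenerate simulation draws")
        tree = pc.sample_tree(leaves, seed, mean_branch_length)
        index = pc.TreeIndex.from_tree(tree)
        table = pc.simulate_pair_table(index, params, seed=seed + 10_000_000)
        if table.iloc[:, 0].nunique() < 2 or table.iloc[:, 1].nunique() < 2:
            continue
        fit = pc.validity_screen(pc.fit_ccm(index, table))
        fits.append(fit)
        truth.append(beta12)
    return fits


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture()
def three_leaf_tree():
    return pc.read_newick("(A:0.4,(B:0.3,C:0.7):0.2);")


@pytest.fixture()
def four_leaf_tree():
    return pc.read_newick("((A:0.5,B:0.1):0.3,(C:0.6,D:0.2):0.4);")
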