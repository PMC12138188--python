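"""Newick input and tree normalisation.

The inference core needs a rooted, strictly binary tree with branch lengths
whose leaves cover the genome IDs of the feature table.  This module turns
whatever the user supplies into that shape: midpoint rooting for unrooted
trees, seeded random resolution of multifurcations with zero-length edges,
and pruning of leaves absent from the feature table.  All operations
preserve leaf-to-leaf path lengths for the leaves they retain.
"""

from __future__ import annotations

import random
from pathlib import Path

import dendropy

from .errors import (
    DegenerateTreeError,
    LabelError,
    MissingLeafError,
    NewickFormatError,
    TreeShapeError,
)


def _leaf_labels(tree: dendropy.Tree) -> list[str]:
    out = []
    for leaf in tree.leaf_node_iter():
        label = leaf.taxon.label if leaf.taxon is not None else leaf.label
        out.append(label)
    return out


def _validate(tree: dendropy.Tree) -> dendropy.Tree:
    labels = _leaf_labels(tree)
    if any(lbl is None or lbl == "" for lbl in labels):
        raise LabelError("every leaf must carry a nonempty label")
    dupes = sorted({l for l in labels if labels.count(l) > 1})
    if dupes:
        raise LabelError(f"duplicate leaf labels: {dupes}")
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        if node.edge.length is None:
            raise NewickFormatError(
                "every edge must carry a branch length (missing lengths are "
                "not imputed)"
            )
        if node.edge.length < 0:
            raise NewickFormatError(
                f"negative branch length {node.edge.length}"
            )
    return tree


def read_newick(source: str | Path) -> dendropy.Tree:
    """Parse a Newick tree from a string or a file path.

    Labels and branch lengths are preserved verbatim (underscores are not
    converted to spaces).  Missing branch lengths and duplicate leaf labels
    are rejected.
    """
    if isinstance(source, Path):
        text = source.read_text()
    elif "(" not in source and ";" not in source:
        text = Path(source).read_text()
    else:
        text = str(source)
    try:
        tree = dendropy.Tree.get(
            data=text, schema="newick", preserve_underscores=True
        )
    except Exception as exc:  # dendropy raises several parse error types
        if "Duplicate taxon labels" in str(exc):
            raise LabelError(f"duplicate leaf labels: {exc}") from exc
        raise NewickFormatError(f"could not parse Newick input: {exc}") from exc
    return _validate(tree)


def write_newick(tree: dendropy.Tree, path: str | Path) -> None:
    """Serialise the tree to a Newick file that re-parses identically."""
    Path(path).write_text(as_newick(tree))


def as_newick(tree: dendropy.Tree) -> str:
    return (
        tree.as_string(
            schema="newick",
            suppress_rooting=True,
            unquoted_underscores=True,
            real_value_format_specifier=".17g",
        ).strip()
        + "\n"
    )


def is_unrooted(tree: dendropy.Tree) -> bool:
    """A tree is treated as unrooted iff its basal node has >= 3 children."""
    return len(tree.seed_node.child_nodes()) >= 3


def _clone(tree: dendropy.Tree) -> dendropy.Tree:
    return tree.clone(depth=1)


def midpoint_root(tree: dendropy.Tree) -> dendropy.Tree:
    """Root an unrooted tree at the midpoint of its longest leaf-to-leaf path.

    An already-rooted tree (basal bifurcation) is returned unchanged.  Ties
    between equally long paths are broken towards the lexicographically
    smallest (sorted) endpoint-label pair, and the walk to the midpoint
    starts from the smaller endpoint, so the placement is deterministic.
    """
    if not is_unrooted(tree):
        return tree
    tree = _clone(tree)

    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
    best = None  # (distance, (label_a, label_b), taxon_a, taxon_b)
    for i, ta in enumerate(taxa):
        for tb in taxa[i + 1 :]:
            d = pdm.patristic_distance(ta, tb)
            key = (ta.label, tb.label)
            if best is None or d > best[0] + 1e-12 or (
                abs(d - best[0]) <= 1e-12 and key < best[1]
            ):
                best = (d, key, ta, tb)
    if best is None or best[0] <= 0:
        raise DegenerateTreeError("no positive leaf-to-leaf path to midpoint-root")
    diameter, _, ta, tb = best

    node_a = tree.find_node_with_taxon_label(ta.label)
    node_b = tree.find_node_with_taxon_label(tb.label)
    path = _path_between(node_a, node_b)

    # Walk from endpoint a towards b until the midpoint falls inside an edge.
    half = diameter / 2.0
    walked = 0.0
    for a_side, child, length in path:
        if walked + length < half - 1e-12:
            walked += length
            continue
        into = half - walked  # distance into this edge from its a-side end
        parent = child.parent_node
        if a_side is child:
            from_child, from_parent = into, length - into
        else:
            from_child, from_parent = length - into, into
        if from_parent <= 1e-12 and parent is not tree.seed_node:
            tree.reroot_at_node(parent, suppress_unifurcations=True)
        elif from_child <= 1e-12 and not child.is_leaf():
            tree.reroot_at_node(child, suppress_unifurcations=True)
        else:
            # dendropy: length1 attaches to the edge's tail (parent) side,
            # length2 to the head (child) side.
            tree.reroot_at_edge(
                child.edge,
                length1=from_parent,
                length2=from_child,
                suppress_unifurcations=True,
            )
        break
    tree.is_rooted = True
    return tree


def _path_between(node_a, node_b):
    """Edges on the path a -> b as (a_side_node, edge_child_node, length).

    ``a_side_node`` is the path endpoint of the edge nearer to ``node_a``;
    ``edge_child_node`` is the edge's child in the tree's own orientation,
    so the caller can hand ``edge_child_node.edge`` to dendropy.
    """
    ancestors_a = []
    n = node_a
    while n is not None:
        ancestors_a.append(n)
        n = n.parent_node
    set_a = {id(x) for x in ancestors_a}
    n = node_b
    while id(n) not in set_a:
        n = n.parent_node
    mrca = n

    path = []
    n = node_a
    while n is not mrca:  # climbing: the a-side endpoint is the child itself
        path.append((n, n, n.edge.length))
        n = n.parent_node
    descend = []
    n = node_b
    while n is not mrca:
        descend.append(n)
        n = n.parent_node
    prev = mrca
    for n in reversed(descend):  # descending: the a-side endpoint is the parent
        path.append((prev, n, n.edge.length))
        prev = n
    return path


def resolve_multifurcations(tree: dendropy.Tree, seed: int = 42) -> dendropy.Tree:
    """Randomly resolve polytomies into binary nodes with zero-length edges.

    Deterministic for a given seed; already-binary trees are returned
    unchanged.  Leaf-to-leaf path lengths are preserved exactly because all
    inserted edges have length zero.
    """
    if is_binary(tree):
        return tree
    tree = _clone(tree)
    tree.resolve_polytomies(limit=2, rng=random.Random(seed))
    for node in tree.preorder_node_iter():
        if node is not tree.seed_node and node.edge.length is None:
            node.edge.length = 0.0
    tree.is_rooted = True
    return tree


def is_binary(tree: dendropy.Tree) -> bool:
    for node in tree.preorder_node_iter():
        if not node.is_leaf() and len(node.child_nodes()) != 2:
            return False
    return True


def enforce_binary(
    tree: dendropy.Tree, strict: bool = False, seed: int = 42
) -> dendropy.Tree:
    """Guarantee a strictly binary tree.

    ``strict=True`` raises on any multifurcation; otherwise multifurcations
    are resolved randomly (seeded) with zero-length edges.
    """
    if is_binary(tree):
        return tree
    if strict:
        raise TreeShapeError(
            "tree is not strictly binary and strict mode is on"
        )
    return resolve_multifurcations(tree, seed=seed)


def reconcile_tips(tree: dendropy.Tree, genome_ids) -> dendropy.Tree:
    """Match tree leaves to the feature table's genome IDs.

    Every genome ID must have a leaf; leaves without a genome ID are pruned,
    with unifurcations suppressed and their edge lengths summed, so the
    retained leaves keep their pairwise path lengths.
    """
    ids = set(genome_ids)
    leaves = set(_leaf_labels(tree))
    missing = sorted(ids - leaves)
    if missing:
        raise MissingLeafError(
            f"genome IDs missing from the tree: {missing}"
        )
    extra = leaves - ids
    if not extra:
        return tree
    tree = _clone(tree)
    tree.retain_taxa_with_labels(sorted(ids), suppress_unifurcations=True)
    # A pruned root can be left with a single child; collapse it into the
    # child so the tree stays strictly binary at the base.
    while len(tree.seed_node.child_nodes()) == 1:
        child = tree.seed_node.child_nodes()[0]
        tree.seed_node = child
        child.parent_node = None
    tree.seed_node.edge.length = None  # no dangling root edge
    tree.purge_taxon_namespace()
    tree.is_rooted = True
    return tree


def normalize_tree(
    tree: dendropy.Tree,
    genome_ids,
    strict_binary: bool = False,
    seed: int = 42,
) -> tuple[dendropy.Tree, list[str]]:
    """Full normalisation pipeline: root, binarise, reconcile.

    Returns the normalised tree and a list of the operations applied, for
    run diagnostics.
    """
    ops: list[str] = []
    if is_unrooted(tree):
        tree = midpoint_root(tree)
        ops.append("midpoint_rooting")
    if not is_binary(tree):
        tree = enforce_binary(tree, strict=strict_binary, seed=seed)
        ops.append("multifurcation_resolution")
    leaves = set(_leaf_labels(tree))
    if leaves - set(genome_ids):
        tree = reconcile_tips(tree, genome_ids)
        ops.append("leaf_pruning")
    else:
        tree = reconcile_tips(tree, genome_ids)
    return tree, ops
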