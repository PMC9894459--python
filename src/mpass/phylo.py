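"""Neighbor-joining trees, Newick serialization, Robinson–Foulds distance.

Trees are held as `skbio.TreeNode` objects; the functions here add the
pieces the pipeline needs on top: a deterministic Saitou–Nei
neighbor-joining implementation (lexicographic tie-breaking, negative branch
lengths clamped to zero), bipartition extraction on the unrooted topology,
and the unweighted Robinson–Foulds symmetric difference used to compare a
metagenomic tree against environmental dendrograms.

Trees are treated as unrooted throughout: the NJ result is rooted, purely
as a representation, at the final three-way join, and bipartitions are
computed on the unrooted topology so the symmetric difference never depends
on where the root was drawn.
"""

from __future__ import annotations

import numpy as np
import skbio
from skbio import TreeNode

from .errors import ParseError, UserInputError

PhyloTree = TreeNode


def nj_tree(dm: skbio.DistanceMatrix) -> TreeNode:
    """Saitou–Nei neighbor joining on a symmetric zero-diagonal matrix.

    At each step the pair (i, j) minimizing the Q-criterion

        Q(i, j) = (n - 2) d(i, j) - sum_k d(i, k) - sum_k d(j, k)

    is joined; branch lengths follow the rate-corrected three-point
    formulas, with negative estimates clamped to 0. Ties on Q are broken
    toward the lexicographically smallest (label_i, label_j) pair so the
    result is reproducible across platforms. The returned tree is unrooted
    (its root is the trifurcation left by the final join).

    Consistency: on an additive matrix NJ recovers the generating topology
    and its exact branch lengths.
    """
    if isinstance(dm, skbio.DistanceMatrix):
        d, ids = np.array(dm.data, dtype=float), list(dm.ids)
    else:
        d = np.array(dm, dtype=float)
        ids = [str(i) for i in range(d.shape[0])]
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise UserInputError("distance matrix must be square")
    if d.shape[0] < 3:
        raise UserInputError("neighbor joining needs at least 3 samples")
    if np.isnan(d).any():
        raise UserInputError("distance matrix contains NaN")
    if (d < 0).any():
        raise UserInputError("distance matrix contains negative entries")
    if not np.allclose(d, d.T):
        raise UserInputError("distance matrix must be symmetric")

    nodes = [TreeNode(name=label) for label in ids]
    # sort key per active node: smallest leaf label under it
    keys = list(ids)

    while len(nodes) > 3:
        n = len(nodes)
        r = d.sum(axis=1)
        q = (n - 2) * d - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        qmin = q.min()
        candidates = [
            tuple(sorted((i, j), key=lambda k: keys[k]))
            for i, j in zip(*np.where(np.isclose(q, qmin, rtol=0, atol=1e-12)))
            if i < j
        ]
        i, j = min(candidates, key=lambda ij: (keys[ij[0]], keys[ij[1]]))
        vi = 0.5 * d[i, j] + (r[i] - r[j]) / (2.0 * (n - 2))
        vj = d[i, j] - vi
        child_i, child_j = nodes[i], nodes[j]
        child_i.length = max(0.0, vi)
        child_j.length = max(0.0, vj)
        parent = TreeNode(children=[child_i, child_j])
        # distances from the new node to the remaining ones
        dk = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        keep = [k for k in range(n) if k not in (i, j)]
        d_new = np.empty((n - 1, n - 1))
        d_new[:-1, :-1] = d[np.ix_(keep, keep)]
        d_new[-1, :-1] = d_new[:-1, -1] = dk[keep]
        d_new[-1, -1] = 0.0
        d = d_new
        nodes = [nodes[k] for k in keep] + [parent]
        keys = [keys[k] for k in keep] + [min(keys[i], keys[j])]

    # final three-point resolution
    (a, b, c) = nodes
    da = max(0.0, 0.5 * (d[0, 1] + d[0, 2] - d[1, 2]))
    db = max(0.0, 0.5 * (d[0, 1] + d[1, 2] - d[0, 2]))
    dc = max(0.0, 0.5 * (d[0, 2] + d[1, 2] - d[0, 1]))
    for node, length in ((a, da), (b, db), (c, dc)):
        node.length = length
    return TreeNode(children=[a, b, c])


def read_newick(source: str) -> TreeNode:
    """Parse a Newick string (or file path) into a tree.

    Raises ``ParseError`` with the character position of the first unbalanced
    parenthesis when the string is malformed.
    """
    text = source
    if "\n" not in source and "(" not in source:
        # looks like a path
        try:
            with open(source) as fh:
                text = fh.read()
        except OSError as exc:
            raise UserInputError(f"cannot read newick input {source!r}: {exc}") from exc
    _check_parens(text)
    try:
        tree = TreeNode.read([text], convert_underscores=False)
    except Exception as exc:  # skbio's format errors
        raise ParseError(f"malformed newick: {exc}") from exc
    return tree


def _check_parens(text: str) -> None:
    depth = 0
    for pos, ch in enumerate(text, 1):
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise ParseError("unbalanced ')' in newick string", line=pos)
    if depth != 0:
        raise ParseError(f"{depth} unclosed '(' in newick string", line=len(text))


def write_newick(tree: TreeNode, path=None) -> str:
    """Serialize a tree to Newick; optionally also write it to ``path``."""
    s = str(tree.write([], format="newick")[0]).strip()
    if path is not None:
        with open(path, "w") as fh:
            fh.write(s + "\n")
    return s


def leaf_labels(tree: TreeNode) -> set[str]:
    return {tip.name for tip in tree.tips()}


def bipartitions(tree: TreeNode) -> frozenset[frozenset[str]]:
    """Non-trivial bipartitions induced by the internal edges of a tree.

    Each internal edge of the unrooted topology splits the leaves in two;
    the split is recorded canonically as the side *not* containing the
    lexicographically smallest leaf label. Trivial splits (one leaf against
    the rest) are excluded, so a star tree yields the empty set and an
    n-leaf binary tree yields n - 3 bipartitions.
    """
    leaves = leaf_labels(tree)
    if len(leaves) != sum(1 for _ in tree.tips()):
        raise UserInputError("duplicate leaf labels in tree")
    ref = min(leaves)
    n = len(leaves)
    splits = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if ref in side:
            side = frozenset(leaves - side)
        if 2 <= len(side) <= n - 2:
            splits.add(side)
    return frozenset(splits)


def rf_symmetric_difference(t1: TreeNode, t2: TreeNode) -> int:
    """Unweighted Robinson–Foulds symmetric difference between two trees.

    Counts bipartitions present in exactly one of the two trees (both taken
    unrooted). 0 means topologically identical; for two fully binary trees
    on n leaves the maximum is 2(n - 3). Multifurcating trees are compared
    on their bipartition sets as-is, without forcing a binary resolution.
    """
    l1, l2 = leaf_labels(t1), leaf_labels(t2)
    if l1 != l2:
        raise UserInputError(
            f"leaf sets differ: only in first {sorted(l1 - l2)}, "
            f"only in second {sorted(l2 - l1)}"
        )
    b1, b2 = bipartitions(t1), bipartitions(t2)
    return len(b1 ^ b2)


def patristic_distances(tree: TreeNode, focal: str) -> dict[str, float]:
    """Path-length (patristic) distance from one leaf to every other leaf."""
    tips = {t.name: t for t in tree.tips()}
    if focal not in tips:
        raise UserInputError(f"leaf {focal!r} not in tree")
    start = tips[focal]
    return {
        name: start.distance(node) for name, node in tips.items() if name != focal
    }


def random_binary_tree(labels: list[str], rng, min_bl: float = 0.1,
                       max_bl: float = 2.0) -> TreeNode:
    """Random unrooted binary tree with uniform random branch lengths.

    Built by sequential random attachment of leaves to a growing unrooted
    topology; used by simulations and oracle tests.
    """
    if len(labels) < 3:
        raise UserInputError("need at least 3 labels")

    def bl():
        return rng.uniform(min_bl, max_bl)

    labels = list(labels)
    root = TreeNode()
    for name in labels[:3]:
        root.append(TreeNode(name=name, length=bl()))
    edges = list(root.children)
    for name in labels[3:]:
        edge = edges[rng.randrange(len(edges))]
        parent = edge.parent
        parent.remove(edge)
        old_len = edge.length
        split = rng.uniform(0.2, 0.8)
        mid = TreeNode(length=old_len * split)
        edge.length = old_len * (1 - split)
        leaf = TreeNode(name=name, length=bl())
        mid.append(edge)
        mid.append(leaf)
        parent.append(mid)
        edges = list(root.traverse(include_self=False))
    return root


def tree_to_distance_matrix(tree: TreeNode) -> skbio.DistanceMatrix:
    """Additive (patristic) distance matrix of a tree's leaves."""
    return tree.tip_tip_distances()
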