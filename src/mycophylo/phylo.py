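"""Tree numerics shared by the structure and signal stages.

Trees are :class:`dendropy.Tree` objects (rooted, branch lengths in
arbitrary but consistent units). This module derives the three numeric
representations the downstream statistics need:

* the cophenetic (patristic) distance matrix, the basis of MPD/MNTD;
* the phylogenetic variance-covariance matrix C, whose entries are
  shared root-to-MRCA path lengths and which encodes the Brownian-motion
  expectation used by Blomberg's K;
* Felsenstein's phylogenetically independent contrasts (PIC), whose
  variance is the permutation-test statistic for phylogenetic signal.

Because the pruning recursion is linear in the tip values, the contrasts
can be written as ``W @ x`` for a fixed (n-1, n) operator ``W``; the
operator form is exposed so permutation nulls can be vectorised.
"""

from __future__ import annotations

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "read_newick",
    "write_newick",
    "tip_labels",
    "tree_depth",
    "cophenetic_distances",
    "vcv_matrix",
    "contrast_operator",
    "independent_contrasts",
]


def read_newick(source: str) -> dendropy.Tree:
    """Read a rooted tree from a Newick file path or string.

    Branch lengths are required downstream; tip labels must be unique.
    """
    from dendropy.dataio.newickreader import NewickReader

    try:
        if "(" in source:
            tree = dendropy.Tree.get(data=source, schema="newick")
        else:
            tree = dendropy.Tree.get(path=source, schema="newick")
    except NewickReader.NewickReaderDuplicateTaxonError as exc:
        raise ValueError(f"duplicate tip labels: {exc}") from exc
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise ValueError(f"duplicate tip labels: {dupes}")
    return tree


def write_newick(tree: dendropy.Tree, path: str) -> None:
    tree.write(path=path, schema="newick", suppress_rooting=True)


def tip_labels(tree: dendropy.Tree) -> list[str]:
    """Tip labels in a stable (postorder) order."""
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def tree_depth(tree: dendropy.Tree) -> float:
    """Maximum root-to-tip path length."""
    return max(leaf.distance_from_root() for leaf in tree.leaf_node_iter())


def _check_tree(tree: dendropy.Tree) -> list:
    leaves = list(tree.leaf_node_iter())
    labels = [l.taxon.label for l in leaves]
    if len(labels) != len(set(labels)):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise ValueError(f"duplicate tip labels: {dupes}")
    return leaves


def _vcv_array(tree: dendropy.Tree) -> tuple[np.ndarray, list[str]]:
    """C[i, j] = root-to-MRCA path length, filled per internal node.

    For each internal node the MRCA of any tip pair split across two of
    its child subtrees is that node, so one postorder pass with numpy
    block assignments covers all pairs.
    """
    leaves = _check_tree(tree)
    labels = [l.taxon.label for l in leaves]
    idx = {leaf: i for i, leaf in enumerate(leaves)}
    n = len(leaves)
    c = np.zeros((n, n))
    tips_below: dict = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            tips_below[node] = [idx[node]]
            c[idx[node], idx[node]] = node.distance_from_root()
            continue
        depth = node.distance_from_root()
        child_tips = [tips_below.pop(ch) for ch in node.child_nodes()]
        for a in range(len(child_tips)):
            for b in range(a + 1, len(child_tips)):
                block = np.ix_(child_tips[a], child_tips[b])
                c[block] = depth
                c[block[::-1]] = depth
        tips_below[node] = [t for ct in child_tips for t in ct]
    return c, labels


def cophenetic_distances(tree: dendropy.Tree) -> pd.DataFrame:
    """Pairwise path-length (patristic) distances between tips.

    Returns a symmetric DataFrame with zero diagonal, indexed by tip
    label in postorder. Derived from the shared-path matrix via
    ``d(i, j) = C[i, i] + C[j, j] - 2 C[i, j]``.
    """
    c, labels = _vcv_array(tree)
    depths = np.diag(c)
    d = depths[:, None] + depths[None, :] - 2.0 * c
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=labels, columns=labels)


def vcv_matrix(tree: dendropy.Tree) -> pd.DataFrame:
    """Phylogenetic variance-covariance matrix C.

    ``C[i, i]`` is the root-to-tip distance of tip i and ``C[i, j]`` the
    root-to-MRCA shared path length, so that for any tree
    ``d(i, j) = C[i, i] + C[j, j] - 2 C[i, j]``.
    """
    c, labels = _vcv_array(tree)
    return pd.DataFrame(c, index=labels, columns=labels)


def _resolve_and_adjust(tree: dendropy.Tree, epsilon_scale: float = 1e-8):
    """Copy of the tree with polytomies bifurcated and zero branches padded.

    Polytomies are resolved arbitrarily with zero-length internal edges;
    all zero-length non-root edges are then raised to
    ``epsilon_scale * tree depth`` so contrast variances stay positive.
    """
    work = tree.clone(depth=1)
    work.resolve_polytomies()
    eps = epsilon_scale * max(tree_depth(work), 1.0)
    for edge in work.preorder_edge_iter():
        if edge.head_node is work.seed_node:
            continue
        if edge.length is None or edge.length <= 0.0:
            edge.length = eps
    return work


def contrast_operator(tree: dendropy.Tree) -> tuple[np.ndarray, list[str]]:
    """Linear operator W mapping tip values to standardized contrasts.

    Runs Felsenstein's pruning algorithm with unit weight vectors in
    place of trait values: at each internal node the contrast is
    ``(xL - xR) / sqrt(vL + vR)`` and the ancestral value is the
    variance-weighted average, with the ancestral branch augmented by
    ``vL vR / (vL + vR)``. Returns ``(W, tip_order)`` with W of shape
    ``(n_tips - 1, n_tips)`` such that ``W @ x`` gives the n-1
    standardized contrasts for trait vector x in ``tip_order``.
    """
    work = _resolve_and_adjust(tree)
    leaves = list(work.leaf_node_iter())
    order = [l.taxon.label for l in leaves]
    n = len(leaves)
    if n < 2:
        raise ValueError("contrasts require at least 2 tips")

    weights: dict = {}
    lengths: dict = {}
    for i, leaf in enumerate(leaves):
        w = np.zeros(n)
        w[i] = 1.0
        weights[leaf] = w
        lengths[leaf] = leaf.edge.length

    rows = []
    for node in work.postorder_node_iter():
        if node.is_leaf():
            continue
        children = node.child_nodes()
        if len(children) != 2:  # resolve_polytomies guarantees this
            raise RuntimeError("tree not bifurcating after resolution")
        left, right = children
        v_l, v_r = lengths[left], lengths[right]
        rows.append((weights[left] - weights[right]) / np.sqrt(v_l + v_r))
        weights[node] = (v_r * weights[left] + v_l * weights[right]) / (v_l + v_r)
        base = node.edge.length if node is not work.seed_node else 0.0
        lengths[node] = (base or 0.0) + v_l * v_r / (v_l + v_r)
    return np.vstack(rows), order


def independent_contrasts(tree: dendropy.Tree, trait: pd.Series) -> np.ndarray:
    """Standardized phylogenetically independent contrasts of a tip trait.

    ``trait`` must supply a finite value for every tip. Under Brownian
    motion with rate sigma^2 the n-1 contrasts are iid N(0, sigma^2).
    """
    w, order = contrast_operator(tree)
    missing = [t for t in order if t not in trait.index]
    if missing:
        raise ValueError(f"trait missing for tips: {missing}")
    x = trait.reindex(order).to_numpy(dtype=float)
    if not np.all(np.isfinite(x)):
        bad = [order[i] for i in np.where(~np.isfinite(x))[0]]
        raise ValueError(f"non-finite trait values for tips: {bad}")
    return w @ x
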