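"""Tree construction and comparison: neighbor joining, newick I/O,
bipartitions and the normalized Robinson-Foulds rate.

Trees are held as :class:`dendropy.Tree` objects treated as unrooted;
dendropy also backs newick parsing/serialization and leaf-to-leaf path
lengths.  The neighbor-joining agglomeration (Saitou & Nei, with the
Q-criterion) and the RF rate are implemented here with deterministic
tie-breaking, so identical inputs always give identical trees.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import dendropy
import numpy as np

from .matrix import MaskedDistanceMatrix

__all__ = [
    "nj_tree",
    "bipartitions",
    "rf_rate",
    "read_newick",
    "parse_newick",
    "write_newick",
    "additive_matrix",
    "leaf_labels",
]

PhyloTree = dendropy.Tree


def leaf_labels(tree: PhyloTree) -> tuple[str, ...]:
    """Leaf taxon labels in the tree's own iteration order."""
    return tuple(lf.taxon.label for lf in tree.leaf_node_iter())


def nj_tree(m: MaskedDistanceMatrix) -> PhyloTree:
    """Neighbor-joining tree from a complete distance matrix.

    Standard agglomeration: at each step the pair minimizing
    Q(i, j) = (r - 2) d(i, j) - S_i - S_j is joined (S_i = row sum over the
    r active nodes); ties broken by the lowest (row, column) index pair.
    Negative branch lengths arising from the formulas are clamped to 0.
    The result is an unrooted tree, binary for N >= 3.
    """
    if not m.is_complete:
        raise ValueError("matrix has missing entries; impute before tree building")
    n = m.n_taxa
    if n < 2:
        raise ValueError("need at least 2 taxa")

    taxa = dendropy.TaxonNamespace([str(lab) for lab in m.labels])
    tree = dendropy.Tree(taxon_namespace=taxa)
    nodes: list[dendropy.Node] = []
    for lab in m.labels:
        node = dendropy.Node(taxon=taxa.get_taxon(str(lab)))
        nodes.append(node)

    d = m.values.astype(float).copy()
    active = list(range(n))

    while len(active) > 3:
        r = len(active)
        sub = d[np.ix_(active, active)]
        sums = sub.sum(axis=1)
        q = (r - 2) * sub - sums[:, None] - sums[None, :]
        # upper triangle only; argmin is row-major, so exact ties resolve
        # to the lowest (row, column) pair
        q[np.tril_indices(r)] = np.inf
        ai, aj = np.unravel_index(int(np.argmin(q)), q.shape)
        i, j = active[ai], active[aj]
        dij = d[i, j]
        li = 0.5 * dij + (sums[ai] - sums[aj]) / (2.0 * (r - 2))
        lj = dij - li
        li, lj = max(0.0, li), max(0.0, lj)

        parent = dendropy.Node()
        parent.add_child(nodes[i])
        nodes[i].edge.length = li
        parent.add_child(nodes[j])
        nodes[j].edge.length = lj

        # distances from the new node to the remaining active nodes
        new_idx = i  # reuse slot i
        for ak in range(r):
            k = active[ak]
            if k in (i, j):
                continue
            d_new = 0.5 * (d[i, k] + d[j, k] - dij)
            d[new_idx, k] = d[k, new_idx] = d_new
        nodes[new_idx] = parent
        active.remove(j)

    if len(active) == 3:
        i, j, k = active
        la = 0.5 * (d[i, j] + d[i, k] - d[j, k])
        lb = 0.5 * (d[i, j] + d[j, k] - d[i, k])
        lc = 0.5 * (d[i, k] + d[j, k] - d[i, j])
        center = dendropy.Node()
        for idx, ln in ((i, la), (j, lb), (k, lc)):
            center.add_child(nodes[idx])
            nodes[idx].edge.length = max(0.0, ln)
        tree.seed_node = center
    else:  # two taxa: a single edge, represented as a midpoint root
        i, j = active
        root = dendropy.Node()
        half = d[i, j] / 2.0
        for idx in (i, j):
            root.add_child(nodes[idx])
            nodes[idx].edge.length = half
        tree.seed_node = root

    tree.is_rooted = False
    return tree


def bipartitions(tree: PhyloTree) -> frozenset[frozenset[str]]:
    """Non-trivial splits of the (unrooted) tree, one per internal edge.

    Each split is canonicalized as the side *not* containing the
    lexicographically smallest leaf label, so split sets from different
    trees over the same taxa are directly comparable.  Trivial splits
    (singleton or full complement) are excluded; duplicate encodings from
    a rooted representation collapse naturally in the returned set.
    """
    labels = set(leaf_labels(tree))
    if len(labels) < 4:
        return frozenset()
    ref = min(labels)
    n = len(labels)
    splits: set[frozenset[str]] = set()
    for node in tree.postorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        below = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if len(below) < 2 or len(below) > n - 2:
            continue
        side = below if ref not in below else frozenset(labels - below)
        splits.add(side)
    return frozenset(splits)


def rf_rate(t1: PhyloTree, t2: PhyloTree) -> float:
    """Normalized Robinson-Foulds distance in [0, 1].

    RF = |B1 symdiff B2| where B1, B2 are the non-trivial split sets; the
    rate divides by |B1| + |B2|, the maximum possible RF, which equals
    2(n - 3) when both trees are binary.  Returns 0 when neither tree has
    internal edges (n <= 3).
    """
    l1, l2 = set(leaf_labels(t1)), set(leaf_labels(t2))
    if l1 != l2:
        raise ValueError(
            f"leaf sets differ: {sorted(l1 ^ l2)} present in only one tree"
        )
    b1, b2 = bipartitions(t1), bipartitions(t2)
    denom = len(b1) + len(b2)
    if denom == 0:
        return 0.0
    return len(b1 ^ b2) / denom


def parse_newick(text: str) -> PhyloTree:
    """Parse a newick string into an unrooted tree."""
    from dendropy.dataio.newickreader import NewickReader

    try:
        tree = dendropy.Tree.get(
            data=text, schema="newick", preserve_underscores=True
        )
    except NewickReader.NewickReaderDuplicateTaxonError as exc:
        raise ValueError("duplicate leaf labels in newick input") from exc
    tree.is_rooted = False
    labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate leaf labels in newick input")
    return tree


def read_newick(path: str | Path) -> PhyloTree:
    """Read one newick tree from a file (treated as unrooted)."""
    return parse_newick(Path(path).read_text())


def write_newick(tree: PhyloTree, path: str | Path | None = None) -> str:
    """Serialize to newick (17-significant-digit branch lengths); optionally
    write to ``path``.  Round trips preserve topology, labels and lengths."""
    text = tree.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
        real_value_format_specifier=".17g",
    )
    if path is not None:
        Path(path).write_text(text)
    return text


def additive_matrix(tree: PhyloTree) -> MaskedDistanceMatrix:
    """Leaf-to-leaf path-length (patristic) distance matrix of a tree."""
    pdm = tree.phylogenetic_distance_matrix()
    leaves = [lf.taxon for lf in tree.leaf_node_iter()]
    labels = tuple(t.label for t in leaves)
    n = len(labels)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i):
            dij = pdm.patristic_distance(leaves[i], leaves[j])
            values[i, j] = values[j, i] = dij
    return MaskedDistanceMatrix(labels, values)
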