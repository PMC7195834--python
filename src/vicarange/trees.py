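"""Rooted-tree indexing shared by the dating, delimitation and biogeography stages.

Trees are read and written with dendropy; :class:`IndexedTree` flattens a
rooted binary dendropy tree into integer arrays so that array-heavy algorithms
(pruning likelihood, MCMC, the DIVA dynamic program) do not pay per-node
object overhead.  Tips get indices ``0..n_tips-1`` in sorted-label order;
internal nodes are appended in postorder, so the root is always the last
index.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import dendropy
import numpy as np

__all__ = [
    "IndexedTree",
    "read_tree",
    "read_trees",
    "tree_to_newick",
    "node_ages",
    "is_ultrametric",
]


def read_tree(source: str) -> dendropy.Tree:
    """Read a single rooted Newick tree from a path or a Newick string."""
    if source.lstrip().startswith("("):
        tree = dendropy.Tree.get(data=source, schema="newick", preserve_underscores=True)
    else:
        tree = dendropy.Tree.get(path=source, schema="newick", preserve_underscores=True)
    tree.is_rooted = True
    return tree


def read_trees(source: str) -> list[dendropy.Tree]:
    """Read a list of rooted Newick trees sharing one taxon namespace."""
    tl = dendropy.TreeList.get(path=source, schema="newick", preserve_underscores=True)
    for t in tl:
        t.is_rooted = True
    return list(tl)


def tree_to_newick(tree: dendropy.Tree) -> str:
    return tree.as_string(schema="newick", suppress_rooting=True).strip()


def node_ages(tree: dendropy.Tree) -> dict[dendropy.Node, float]:
    """Node ages (time before the youngest tip) from edge lengths.

    Works for non-ultrametric trees too, in which case the age of a node is
    the maximum root-to-tip depth minus the node's depth.
    """
    depths: dict[dendropy.Node, float] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            depths[node] = 0.0
        else:
            depths[node] = depths[node.parent_node] + (node.edge.length or 0.0)
    height = max(depths[leaf] for leaf in tree.leaf_node_iter())
    return {node: height - depth for node, depth in depths.items()}


def is_ultrametric(tree: dendropy.Tree, tol: float = 1e-6) -> bool:
    depths: dict[dendropy.Node, float] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            depths[node] = 0.0
        else:
            depths[node] = depths[node.parent_node] + (node.edge.length or 0.0)
    tip_depths = [depths[leaf] for leaf in tree.leaf_node_iter()]
    return max(tip_depths) - min(tip_depths) <= tol


class IndexedTree:
    """Array view of a rooted binary tree.

    Attributes
    ----------
    tip_labels : list of str, tips in index order (sorted).
    n_tips, n_nodes : int; ``n_nodes == 2 * n_tips - 1``.
    parent : int array of length ``n_nodes``; root has parent ``-1``.
    children : ``(n_internal, 2)`` int array indexed by ``node - n_tips``.
    postorder_internal : internal node indices in postorder (root last).
    edge_length : float array; length of the edge above each node (root nan).
    clades : list of frozensets of tip indices per node.
    """

    def __init__(self, tree: dendropy.Tree):
        leaves = sorted(tree.leaf_node_iter(), key=lambda nd: nd.taxon.label)
        internals = [nd for nd in tree.postorder_node_iter() if not nd.is_leaf()]
        for nd in internals:
            if len(nd.child_nodes()) != 2:
                raise ValueError("tree must be strictly bifurcating")
        self.tip_labels = [nd.taxon.label for nd in leaves]
        if len(set(self.tip_labels)) != len(self.tip_labels):
            raise ValueError("duplicate tip labels")
        self.n_tips = len(leaves)
        self.n_nodes = 2 * self.n_tips - 1
        index = {nd: i for i, nd in enumerate(leaves)}
        for j, nd in enumerate(internals):
            index[nd] = self.n_tips + j
        self.parent = np.full(self.n_nodes, -1, dtype=int)
        self.children = np.zeros((self.n_tips - 1, 2), dtype=int)
        self.edge_length = np.full(self.n_nodes, np.nan)
        for nd, i in index.items():
            if nd.parent_node is not None:
                self.parent[i] = index[nd.parent_node]
                self.edge_length[i] = nd.edge.length if nd.edge.length is not None else np.nan
            if not nd.is_leaf():
                left, right = nd.child_nodes()
                self.children[i - self.n_tips] = (index[left], index[right])
        self.postorder_internal = np.array([index[nd] for nd in internals], dtype=int)
        self.root = self.n_tips + len(internals) - 1
        clades: list[frozenset[int]] = [frozenset([i]) for i in range(self.n_tips)]
        for i in self.postorder_internal:
            l, r = self.children[i - self.n_tips]
            clades.append(clades[l] | clades[r])
        self.clades = clades
        self._node_of = index

    def node_index(self, node: dendropy.Node) -> int:
        return self._node_of[node]

    def mrca(self, labels: Iterable[str]) -> int:
        """Index of the most recent common ancestor of the given tip labels."""
        want = frozenset(self.tip_labels.index(lbl) for lbl in labels)
        best = None
        for i in range(self.n_tips, self.n_nodes):
            if want <= self.clades[i]:
                if best is None or len(self.clades[i]) < len(self.clades[best]):
                    best = i
        if best is None:
            raise KeyError(f"no common ancestor found for {sorted(labels)}")
        return best

    def clade_labels(self, node: int) -> frozenset[str]:
        return frozenset(self.tip_labels[i] for i in self.clades[node])

    def ages_from_edges(self) -> np.ndarray:
        """Node ages from edge lengths (requires an ultrametric tree)."""
        depth = np.zeros(self.n_nodes)
        order = list(self.postorder_internal[::-1])
        for i in order:
            for c in self.children[i - self.n_tips]:
                depth[c] = depth[i] + self.edge_length[c]
        height = depth[: self.n_tips].max()
        return height - depth

    def newick_with_ages(self, ages: Sequence[float], label_internal: bool = False) -> str:
        """Serialize to Newick with edge lengths derived from node ages."""
        ages = np.asarray(ages, dtype=float)

        def render(i: int) -> str:
            if i < self.n_tips:
                return self.tip_labels[i]
            l, r = self.children[i - self.n_tips]
            parts = []
            for c in (l, r):
                bl = ages[i] - ages[c]
                parts.append(f"{render(c)}:{bl:.10g}")
            name = f"n{i}" if label_internal else ""
            return f"({parts[0]},{parts[1]}){name}"

        return render(self.root) + ";"
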