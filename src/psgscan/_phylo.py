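"""Indexed phylogeny wrapper used by the likelihood engine and the simulator.

Trees come in as Newick (parsed by dendropy) and are flattened into
postorder arrays: one edge per non-root node, identified by the child
node's index.  Tips occupy indices ``0 .. n_tips-1`` in the order of
``tip_labels``; internal nodes follow in postorder; the root is last.
An unrooted tree written with a trifurcating root is accepted as-is;
any other polytomy is rejected because the likelihood machinery assumes
a resolved topology.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np


class PolytomyError(ValueError):
    """Raised when a tree contains an unresolved internal node."""


@dataclass
class IndexedTree:
    tip_labels: list[str]
    #: parent index for every node (root's parent is -1)
    parent: np.ndarray
    #: branch length above every node (root entry is 0.0)
    length: np.ndarray
    #: node indices in postorder (children before parents, root last)
    postorder: np.ndarray
    children: list[list[int]] = field(repr=False)

    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def root(self) -> int:
        return int(self.postorder[-1])

    def tip_index(self, label: str) -> int:
        return self.tip_labels.index(label)

    @property
    def tree_length(self) -> float:
        """Sum of branch lengths (expected substitutions per codon)."""
        return float(self.length.sum())

    # -- construction ------------------------------------------------------

    @classmethod
    def from_newick(cls, newick: str) -> "IndexedTree":
        tree = dendropy.Tree.get(data=newick, schema="newick",
                                 preserve_underscores=True)
        return cls.from_dendropy(tree)

    @classmethod
    def from_dendropy(cls, tree: dendropy.Tree) -> "IndexedTree":
        root = tree.seed_node
        for node in tree.preorder_node_iter():
            n_children = len(node.child_nodes())
            if node is root:
                # degenerate 0/1-child roots arise for single-taxon trees
                if n_children not in (0, 1, 2, 3):
                    raise PolytomyError(
                        f"root has {n_children} children; expected 2 (rooted) "
                        "or 3 (unrooted)")
            elif n_children not in (0, 2):
                raise PolytomyError("tree contains an unresolved polytomy")

        tips = [lf for lf in tree.leaf_node_iter()]
        tip_labels = [lf.taxon.label for lf in tips]
        index = {id(lf): i for i, lf in enumerate(tips)}
        internal = [nd for nd in tree.postorder_internal_node_iter()]
        for off, nd in enumerate(internal):
            index[id(nd)] = len(tips) + off

        n = len(tips) + len(internal)
        parent = np.full(n, -1, dtype=np.int64)
        length = np.zeros(n, dtype=float)
        children: list[list[int]] = [[] for _ in range(n)]
        for nd in tree.preorder_node_iter():
            i = index[id(nd)]
            if nd.parent_node is not None:
                parent[i] = index[id(nd.parent_node)]
                children[parent[i]].append(i)
                length[i] = float(nd.edge.length or 0.0)
        post = np.array([index[id(nd)] for nd in tree.postorder_node_iter()],
                        dtype=np.int64)
        return cls(tip_labels, parent, length, post, children)

    # -- output ------------------------------------------------------------

    def to_newick(self, precision: int = 10) -> str:
        def fmt(i: int) -> str:
            if i < self.n_tips:
                core = self.tip_labels[i]
            else:
                core = "(" + ",".join(fmt(c) for c in self.children[i]) + ")"
            if self.parent[i] == -1:
                return core
            return f"{core}:{self.length[i]:.{precision}g}"

        return fmt(self.root) + ";"

    def with_lengths(self, lengths: np.ndarray) -> "IndexedTree":
        out = IndexedTree(list(self.tip_labels), self.parent.copy(),
                          np.asarray(lengths, dtype=float).copy(),
                          self.postorder.copy(),
                          [list(c) for c in self.children])
        return out

    def scaled(self, factor: float) -> "IndexedTree":
        return self.with_lengths(self.length * factor)


def random_tree(taxa: list[str], rng: np.random.Generator,
                tree_length: float = 3.0) -> IndexedTree:
    """Random bifurcating rooted topology with exponential branch lengths
    rescaled so the total length equals ``tree_length``."""
    newicks = [f"{t}" for t in taxa]
    avail = list(newicks)
    while len(avail) > 1:
        i, j = rng.choice(len(avail), size=2, replace=False)
        a, b = avail[i], avail[j]
        la, lb = rng.exponential(1.0, size=2)
        merged = f"({a}:{la:.6f},{b}:{lb:.6f})"
        avail = [x for k, x in enumerate(avail) if k not in (i, j)] + [merged]
    tree = IndexedTree.from_newick(avail[0] + ";")
    total = tree.tree_length
    if total > 0:
        tree = tree.scaled(tree_length / total)
    return tree
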