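"""Array encoding of rooted binary trees.

Metrics and null-model simulation repeatedly traverse the same family
subtree (up to thousands of tips, a thousand simulation replicates), so the
dendropy object tree is compiled once into flat index arrays: tips are
nodes ``0..n_tips-1`` (in a stable traversal order), internal nodes follow,
and every internal node stores its two children. All per-replicate work is
then vectorised numpy on these arrays.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np

__all__ = ["TreeIndex", "tree_from_newick"]


def tree_from_newick(source: str) -> dendropy.Tree:
    """Parse a Newick string into a rooted dendropy tree.

    Underscores in labels are preserved literally (not turned into spaces),
    so tip names round-trip against taxonomy tables.
    """
    tree = dendropy.Tree.get(data=source, schema="newick", preserve_underscores=True)
    tree.is_rooted = True
    return tree


@dataclass
class TreeIndex:
    """Flat-array view of a rooted, fully bifurcating tree.

    Attributes
    ----------
    n_tips : int
        Number of leaves; leaves occupy node ids ``0..n_tips-1``.
    labels : tuple of str
        Tip labels, ``labels[i]`` names tip node ``i``.
    children : (n_internal, 2) int array
        Children of internal node ``n_tips + j`` are ``children[j]``.
    parent : (n_nodes,) int array
        Parent node id; ``-1`` for the root.
    postorder_internal : (n_internal,) int array
        Internal node ids in postorder (children always precede parents).
    """

    n_tips: int
    labels: tuple
    children: np.ndarray
    parent: np.ndarray
    postorder_internal: np.ndarray
    _label_to_id: dict = field(default=None, repr=False)

    def __post_init__(self):
        if self._label_to_id is None:
            self._label_to_id = {lbl: i for i, lbl in enumerate(self.labels)}

    @property
    def n_nodes(self) -> int:
        return self.parent.shape[0]

    @property
    def root(self) -> int:
        return int(np.flatnonzero(self.parent == -1)[0])

    @classmethod
    def from_dendropy(cls, tree: dendropy.Tree) -> "TreeIndex":
        """Compile a dendropy tree; raises ValueError on polytomies or unifurcations."""
        leaves = []
        internals = []
        for nd in tree.postorder_node_iter():
            kids = nd.child_nodes()
            if not kids:
                leaves.append(nd)
            elif len(kids) == 2:
                internals.append(nd)
            else:
                raise ValueError(
                    f"tree is not fully bifurcating: node with {len(kids)} children"
                )
        n_tips = len(leaves)
        if n_tips < 2:
            raise ValueError("tree must have at least 2 tips")
        ids = {}
        labels = []
        for i, nd in enumerate(leaves):
            ids[id(nd)] = i
            lbl = nd.taxon.label if nd.taxon is not None else nd.label
            if lbl is None:
                raise ValueError("unlabeled tip")
            labels.append(lbl)
        if len(set(labels)) != n_tips:
            raise ValueError("tip labels are not unique")
        for j, nd in enumerate(internals):
            ids[id(nd)] = n_tips + j
        n_nodes = n_tips + len(internals)
        children = np.empty((len(internals), 2), dtype=np.int64)
        parent = np.full(n_nodes, -1, dtype=np.int64)
        for j, nd in enumerate(internals):
            c1, c2 = nd.child_nodes()
            children[j, 0] = ids[id(c1)]
            children[j, 1] = ids[id(c2)]
            parent[children[j, 0]] = n_tips + j
            parent[children[j, 1]] = n_tips + j
        # internals were collected in postorder, so id order == postorder
        return cls(
            n_tips=n_tips,
            labels=tuple(labels),
            children=children,
            parent=parent,
            postorder_internal=np.arange(n_tips, n_nodes, dtype=np.int64),
        )

    def tip_id(self, label: str) -> int:
        return self._label_to_id[label]

    def states_vector(self, states: dict) -> np.ndarray:
        """Turn a tip-label -> {0,1} mapping into a 0/1 vector in tip-id order.

        The mapping's domain must equal the tree's tip set exactly.
        """
        missing = [l for l in self.labels if l not in states]
        if missing:
            raise ValueError(f"states missing for tips: {missing[:5]} ...")
        extra = set(states) - set(self.labels)
        if extra:
            raise ValueError(f"states given for unknown tips: {sorted(extra)[:5]} ...")
        vec = np.array([states[l] for l in self.labels], dtype=np.int64)
        if not np.isin(vec, (0, 1)).all():
            raise ValueError("states must be 0 or 1")
        return vec

    def accumulate_down(self, increments: np.ndarray) -> np.ndarray:
        """Cumulative sums root->tips: value[v] = value[parent] + increments[v].

        ``increments`` has shape (n_nodes, m); the root's own increment is
        ignored (the root value is fixed at 0). Returns the same shape.
        """
        values = np.array(increments, dtype=np.float64, copy=True)
        values[self.root] = 0.0
        for v in self.postorder_internal[::-1]:
            row = self.children[v - self.n_tips]
            values[row[0]] += values[v]
            values[row[1]] += values[v]
        return values
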