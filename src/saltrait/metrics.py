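"""Phylogenetic pattern metrics for a binary trait on a rooted binary tree.

Two statistics summarise how a rare binary trait (here: salt tolerance,
1 = halophyte) is arranged on a family subtree:

* **NoTO** (number of tips per origin): the number of trait-positive tips
  divided by the minimum number of independent gains needed to explain
  their arrangement. Gains and losses cost equally; among all
  minimum-change ancestral reconstructions the one with the fewest gains
  is chosen, because the question asked is "how few origins suffice".
  A gain at the root (trait present ancestrally) counts as one origin.
* **SSCD** (sum of sister clade differences): each internal node is scored
  with the mean of its two children's scores (tips score 0/1); SSCD is the
  sum over internal nodes of the absolute difference between the two child
  scores. Scattered trait tips give a large SSCD, one compact clade a
  small one.

Both are defined only on fully bifurcating trees with every branch length
equal; polytomy resolution and branch-length flattening live upstream in
:mod:`saltrait.treeprep`.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np

from .phylo import TreeIndex

__all__ = [
    "OriginReconstruction",
    "MetricResult",
    "NoOriginsError",
    "parsimony_origins",
    "noto",
    "sscd",
    "compute_metrics",
    "min_gains_batch",
    "sscd_batch",
]

# lexicographic (changes, gains) cost packed into one int: changes * _BIG + gains
_BIG = 1 << 20
_INF = 1 << 60


class NoOriginsError(ValueError):
    """Raised when a tree carries no trait-positive tips (NoTO undefined)."""


@dataclass(frozen=True)
class OriginReconstruction:
    """A minimum-change, gains-minimal ancestral reconstruction."""

    n_gains: int
    n_losses: int
    gain_edges: frozenset  # node ids whose stem edge carries a 0->1 change
    node_states: np.ndarray  # (n_nodes,) 0/1 assignment achieving the minimum

    @property
    def n_changes(self) -> int:
        return self.n_gains + self.n_losses


@dataclass(frozen=True)
class MetricResult:
    n_halophyte_tips: int
    n_gains: int
    n_losses: int
    noto: float
    sscd: float


def _as_index(tree) -> TreeIndex:
    if isinstance(tree, TreeIndex):
        return tree
    if isinstance(tree, dendropy.Tree):
        return TreeIndex.from_dendropy(tree)
    raise TypeError(f"expected TreeIndex or dendropy.Tree, got {type(tree)!r}")


def _as_states(index: TreeIndex, states) -> np.ndarray:
    if isinstance(states, dict):
        return index.states_vector(states)
    vec = np.asarray(states, dtype=np.int64)
    if vec.shape != (index.n_tips,):
        raise ValueError("state vector length must equal the number of tips")
    return vec


def _dp_costs(index: TreeIndex, states: np.ndarray) -> np.ndarray:
    """Packed (changes, gains) DP table, shape (n_nodes, 2, m).

    ``states`` is (n_tips,) or (n_tips, m). The tree is treated as hanging
    from a virtual state-0 ancestor, so a trait-positive root contributes
    one change and one gain; this makes "present since the root" count as a
    single origin.
    """
    states = np.atleast_2d(states.T).T  # (n_tips, m)
    m = states.shape[1]
    cost = np.full((index.n_nodes, 2, m), _INF, dtype=np.int64)
    tip_rows = np.arange(index.n_tips)[:, None]
    cost[tip_rows, states, np.arange(m)[None, :]] = 0  # observed tip state costs 0
    # pen[s][t]: cost of an edge parent-state s -> child-state t
    pen = np.array([[0, _BIG + 1], [_BIG, 0]], dtype=np.int64)
    for v in index.postorder_internal:
        c1, c2 = index.children[v - index.n_tips]
        for s in (0, 1):
            acc = np.minimum(cost[c1, 0] + pen[s, 0], cost[c1, 1] + pen[s, 1])
            acc += np.minimum(cost[c2, 0] + pen[s, 0], cost[c2, 1] + pen[s, 1])
            cost[v, s] = acc
    return cost


def min_gains_batch(index: TreeIndex, states: np.ndarray) -> np.ndarray:
    """Minimum-change, gains-minimal gain counts for many state columns at once.

    ``states`` is (n_tips, m); returns an (m,) int vector of gain counts.
    Columns with zero positive tips get 0 gains.
    """
    cost = _dp_costs(index, states)
    root = index.root
    pen_root = np.array([0, _BIG + 1], dtype=np.int64)
    total = np.minimum(cost[root, 0] + pen_root[0], cost[root, 1] + pen_root[1])
    return (total % _BIG).astype(np.int64)


def parsimony_origins(tree, states) -> OriginReconstruction:
    """Infer the minimum gains/losses explaining the tip states.

    Equal-cost parsimony on the bifurcating tree; among all minimum-total-
    change reconstructions, one minimising the number of 0->1 edges is
    returned (counting a state-1 root as a gain on its stem).
    """
    index = _as_index(tree)
    vec = _as_states(index, states)
    if vec.sum() == 0:
        raise NoOriginsError("no trait-positive tips: origin count undefined")
    cost = _dp_costs(index, vec)[:, :, 0]
    root = index.root
    pen = np.array([[0, _BIG + 1], [_BIG, 0]], dtype=np.int64)
    totals = [cost[root, 0] + pen[0, 0], cost[root, 1] + pen[0, 1]]
    root_state = int(np.argmin(totals))
    total = int(totals[root_state])
    n_gains = total % _BIG
    n_changes = total // _BIG
    # backtrack one optimal assignment, top-down
    node_states = np.empty(index.n_nodes, dtype=np.int64)
    node_states[: index.n_tips] = vec
    node_states[root] = root_state
    for v in index.postorder_internal[::-1]:
        s = node_states[v]
        for c in index.children[v - index.n_tips]:
            if c < index.n_tips:
                continue
            node_states[c] = int(
                np.argmin([cost[c, 0] + pen[s, 0], cost[c, 1] + pen[s, 1]])
            )
    gain_edges = set()
    if root_state == 1:
        gain_edges.add(root)
    for v in range(index.n_nodes):
        p = index.parent[v]
        if p >= 0 and node_states[p] == 0 and node_states[v] == 1:
            gain_edges.add(v)
    assert len(gain_edges) == n_gains, "backtrack disagrees with DP gain count"
    return OriginReconstruction(
        n_gains=int(n_gains),
        n_losses=int(n_changes - n_gains),
        gain_edges=frozenset(int(v) for v in gain_edges),
        node_states=node_states,
    )


def noto(tree, states) -> float:
    """Number of tips per origin: trait-positive tip count / inferred gains."""
    index = _as_index(tree)
    vec = _as_states(index, states)
    rec = parsimony_origins(index, vec)
    return float(vec.sum()) / rec.n_gains


def sscd_batch(index: TreeIndex, states: np.ndarray) -> np.ndarray:
    """Sum of sister clade differences for many state columns, shape (m,)."""
    states = np.atleast_2d(states.T).T
    m = states.shape[1]
    values = np.zeros((index.n_nodes, m), dtype=np.float64)
    values[: index.n_tips] = states
    out = np.zeros(m, dtype=np.float64)
    for v in index.postorder_internal:
        c1, c2 = index.children[v - index.n_tips]
        out += np.abs(values[c1] - values[c2])
        values[v] = 0.5 * (values[c1] + values[c2])
    return out


def sscd(tree, states) -> float:
    """Sum over internal nodes of |left child score - right child score|."""
    index = _as_index(tree)
    vec = _as_states(index, states)
    return float(sscd_batch(index, vec)[0])


def compute_metrics(tree, states) -> MetricResult:
    """NoTO and SSCD together, sharing one compiled tree."""
    index = _as_index(tree)
    vec = _as_states(index, states)
    rec = parsimony_origins(index, vec)
    k = int(vec.sum())
    return MetricResult(
        n_halophyte_tips=k,
        n_gains=rec.n_gains,
        n_losses=rec.n_losses,
        noto=k / rec.n_gains,
        sscd=float(sscd_batch(index, vec)[0]),
    )
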