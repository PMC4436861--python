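"""Independent brute-force oracles used by the test suite.

These deliberately re-derive the statistics from first principles
(exhaustive enumeration, direct mass summation, O(n^2) pair counting) and
share no code path with the package's implementations.
"""

from __future__ import annotations

from math import comb

import numpy as np


def brute_parsimony(index, states) -> tuple[int, int]:
    """(min_changes, min_gains_among_min_change) by exhaustive enumeration.

    Enumerates every 0/1 assignment to the internal nodes, counts state
    changes on every edge plus a virtual edge from a state-0 ancestor to
    the root (so a trait-positive root costs one change and one gain), and
    minimises (changes, gains) lexicographically.
    """
    states = np.asarray(states, dtype=np.int64)
    n_tips, n_nodes = index.n_tips, index.n_nodes
    n_int = n_nodes - n_tips
    m = 1 << n_int
    labelings = (np.arange(m)[:, None] >> np.arange(n_int)[None, :]) & 1
    full = np.empty((m, n_nodes), dtype=np.int64)
    full[:, :n_tips] = states
    full[:, n_tips:] = labelings
    changes = np.zeros(m, dtype=np.int64)
    gains = np.zeros(m, dtype=np.int64)
    for v in range(n_nodes):
        p = index.parent[v]
        if p == -1:
            changes += full[:, v] == 1
            gains += full[:, v] == 1
        else:
            diff = full[:, p] != full[:, v]
            changes += diff
            gains += diff & (full[:, v] == 1)
    key = changes * (n_nodes + 1) + gains
    best = int(np.argmin(key))
    return int(changes[best]), int(gains[best])


def brute_sscd(index, states) -> float:
    """SSCD by direct recursion over the node structure."""
    states = np.asarray(states, dtype=float)

    def value(v):
        if v < index.n_tips:
            return states[v], 0.0
        c1, c2 = index.children[v - index.n_tips]
        v1, s1 = value(c1)
        v2, s2 = value(c2)
        return 0.5 * (v1 + v2), s1 + s2 + abs(v1 - v2)

    return value(index.root)[1]


def brute_binomial_tails(k: int, n: int, p: float) -> tuple[float, float]:
    """Tail probabilities by direct summation of the binomial mass."""
    pmf = [comb(n, i) * p**i * (1 - p) ** (n - i) for i in range(n + 1)]
    return sum(pmf[k:]), sum(pmf[: k + 1])


def brute_kendall_tau_b(x, y) -> float:
    """Tau-b by O(n^2) concordant/discordant pair counting with tie terms."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    conc = disc = 0
    for i in range(n):
        for j in range(i + 1, n):
            dx, dy = x[i] - x[j], y[i] - y[j]
            if dx * dy > 0:
                conc += 1
            elif dx * dy < 0:
                disc += 1
    n0 = n * (n - 1) / 2
    denom = np.sqrt((n0 - _tie_term(x)) * (n0 - _tie_term(y)))
    return (conc - disc) / denom


def _tie_term(v) -> float:
    _, counts = np.unique(v, return_counts=True)
    return float((counts * (counts - 1) / 2).sum())
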