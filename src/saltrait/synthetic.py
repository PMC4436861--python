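"""Synthetic trees, trait maps and family tables with known ground truth.

The real analysis runs on a GenBank-wide angiosperm phylogeny, a curated
halophyte list and APG family sizes — none of which ship with the package.
This module generates stand-ins with the statistical structure the
pipeline assumes, so every downstream stage can be exercised and verified
against planted truth:

* Yule (pure-birth) topologies with every branch length set to 1, the
  equal-branch-length convention the metrics require. The Yule topology
  is an explicit modelling stand-in for the real tree shape.
* Binary trait maps with a *planted* number of origins: trait-positive
  tips arranged as disjoint clades whose placement is verified to be
  recovered exactly (m gains, 0 losses) by minimum-change reconstruction.
* Family tables whose halophyte counts are Binomial(n_i, p·e_i) draws,
  with log-normal family sizes (heavy right tail, like real families that
  span two orders of magnitude to tens of thousands of species) and
  optional per-family enrichment/depletion factors e_i.
* Dirty tip-name lists (indeterminate epithets, hybrid formats) with
  ground-truth keep/drop flags for exercising the name filters.

Every function takes an explicit seed and is bit-reproducible; no global
random state is touched.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np

from .diversity import FamilyRecord
from .metrics import parsimony_origins
from .phylo import TreeIndex
from .treeprep import set_unit_branch_lengths

__all__ = [
    "SimConfig",
    "InfeasiblePlacementError",
    "generate_yule_tree",
    "plant_origins",
    "generate_family_table",
    "generate_dirty_tip_names",
]

# log family-size distribution: exp(mu + sigma^2/2) ~ 672 species/family,
# the mean implied by ~276k species over 411 families, with a heavy tail
_SIZE_MU = 5.4
_SIZE_SIGMA = 1.5


class InfeasiblePlacementError(RuntimeError):
    """No trait placement with the requested origin structure exists."""


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one synthetic study.

    Defaults mirror the real study's conditions: a global halophyte
    proportion near 1%, 411 families, and family subtrees of a few
    hundred tips.
    """

    n_tips: int = 200
    n_families: int = 411
    global_p: float = 0.0103
    planted_origins: int = 5
    k_halophytes: int = 20
    seed: int = 0
    enrichment: float = 1.0

    def __post_init__(self):
        if self.n_tips < 2:
            raise ValueError("n_tips must be >= 2")
        if self.n_families < 1:
            raise ValueError("n_families must be >= 1")
        if not 0.0 < self.global_p < 1.0:
            raise ValueError("global_p must be in (0, 1)")
        if self.planted_origins < 0:
            raise ValueError("planted_origins must be >= 0")
        if not 0 <= self.k_halophytes <= self.n_tips:
            raise ValueError("k_halophytes must be in [0, n_tips]")
        if self.planted_origins > 0 and self.k_halophytes < self.planted_origins:
            raise ValueError("k_halophytes must be >= planted_origins")


def generate_yule_tree(n_tips: int, seed: int) -> dendropy.Tree:
    """Seeded pure-birth topology with every branch length equal to 1.

    Grown by repeatedly bifurcating a uniformly chosen extant leaf — the
    Yule process's topology distribution — then flattening all branch
    lengths to 1, since the downstream metrics use edge counts, not time.
    Tip labels are ``t0001``-style, unique, and fully determined by the
    seed.
    """
    if n_tips < 2:
        raise ValueError("n_tips must be >= 2")
    rng = np.random.default_rng(seed)
    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.is_rooted = True
    left, right = dendropy.Node(), dendropy.Node()
    tree.seed_node.add_child(left)
    tree.seed_node.add_child(right)
    leaves = [left, right]
    while len(leaves) < n_tips:
        i = int(rng.integers(len(leaves)))
        node = leaves[i]
        a, b = dendropy.Node(), dendropy.Node()
        node.add_child(a)
        node.add_child(b)
        leaves[i] = a
        leaves.append(b)
    width = max(4, len(str(n_tips)))
    for j, leaf in enumerate(leaves, start=1):
        leaf.taxon = taxa.new_taxon(label=f"t{j:0{width}d}")
    set_unit_branch_lengths(tree)
    return tree


def _clade_masks(index: TreeIndex) -> list[tuple[int, int, int]]:
    """(node_id, size, tip bitmask) for every non-root node."""
    masks = np.zeros(index.n_nodes, dtype=object)
    for t in range(index.n_tips):
        masks[t] = 1 << t
    for v in index.postorder_internal:
        c1, c2 = index.children[v - index.n_tips]
        masks[v] = masks[c1] | masks[c2]
    root = index.root
    out = []
    for v in range(index.n_nodes):
        if v == root:
            continue
        m = masks[v]
        out.append((v, int(m).bit_count(), int(m)))
    return out


def plant_origins(tree, planted_origins: int, k_halophytes: int, seed: int) -> dict:
    """Trait map with exactly ``planted_origins`` recoverable gains.

    Picks ``planted_origins`` disjoint clades whose tip counts sum to
    ``k_halophytes`` and marks their tips state 1. Candidate placements
    require every chosen clade's sister subtree to retain a state-0 tip
    (stem separation), and each placement is verified to reconstruct to
    exactly (m gains, 0 losses) under minimum-change parsimony before
    being returned; placements where a root-state-1 labeling could tie are
    thereby rejected rather than silently accepted.

    Raises :class:`InfeasiblePlacementError` when bounded search finds no
    valid placement, and ValueError for ``planted_origins < 1``.
    """
    if planted_origins < 1:
        raise ValueError("planted_origins must be >= 1")
    if k_halophytes < planted_origins:
        raise ValueError("k_halophytes must be >= planted_origins")
    index = tree if isinstance(tree, TreeIndex) else TreeIndex.from_dendropy(tree)
    if k_halophytes > index.n_tips:
        raise ValueError("k_halophytes exceeds the number of tips")
    rng = np.random.default_rng(seed)
    all_masks = _clade_masks(index)
    cands = [c for c in all_masks if c[1] <= k_halophytes - planted_origins + 1]
    masks = {v: m for v, _, m in all_masks}
    sibling_mask = {}
    for v, _, _ in cands:
        p = index.parent[v]
        c1, c2 = index.children[p - index.n_tips]
        sib = int(c2 if c1 == v else c1)
        sibling_mask[v] = masks.get(sib, 0)

    # randomized greedy with full restarts: pick disjoint, non-adjacent
    # clades until m are chosen summing exactly to k, then verify with the
    # parsimony DP; thousands of cheap attempts beat deep backtracking here
    order = list(cands)
    n_attempts = 3000
    for _attempt in range(n_attempts):
        rng.shuffle(order)
        chosen: list[tuple[int, int, int]] = []
        union = 0
        remaining = k_halophytes
        for v, size, m in order:
            slots_left = planted_origins - len(chosen)
            if slots_left == 0:
                break
            if size > remaining - (slots_left - 1):
                continue
            if m & union:
                continue
            tentative = union | m
            sib = sibling_mask[v]
            if sib and sib & ~tentative == 0:
                continue  # would leave this clade's sister fully trait-positive
            if any(
                sibling_mask[u] and sibling_mask[u] & ~tentative == 0
                for u, _, _ in chosen
            ):
                continue  # would engulf a previously chosen clade's sister
            chosen.append((v, size, m))
            union = tentative
            remaining -= size
        if len(chosen) != planted_origins or remaining != 0:
            continue
        states = np.zeros(index.n_tips, dtype=np.int64)
        for t in range(index.n_tips):
            if union >> t & 1:
                states[t] = 1
        rec = parsimony_origins(index, states)
        if rec.n_gains == planted_origins and rec.n_losses == 0:
            return {index.labels[t]: int(states[t]) for t in range(index.n_tips)}
    raise InfeasiblePlacementError(
        f"no placement of {planted_origins} separated origins covering "
        f"{k_halophytes} tips found on this {index.n_tips}-tip tree "
        f"within {n_attempts} attempts"
    )


def generate_family_table(
    n_families: int,
    global_p: float,
    seed: int,
    enrichment=None,
) -> list[FamilyRecord]:
    """Family table with Binomial(n_i, min(1, p·e_i)) halophyte counts.

    Family sizes are log-normal (heavy tail) rounded to integers and
    truncated at 1. ``enrichment`` is 1 (null) by default, or a scalar or
    per-family sequence of multiplicative factors >= 0.
    """
    if n_families < 1:
        raise ValueError("n_families must be >= 1")
    if not 0.0 < global_p < 1.0:
        raise ValueError("global_p must be in (0, 1)")
    if enrichment is None:
        factors = np.ones(n_families)
    else:
        factors = np.broadcast_to(np.asarray(enrichment, dtype=float), (n_families,))
        if (factors < 0).any():
            raise ValueError("enrichment factors must be >= 0")
    rng = np.random.default_rng(seed)
    sizes = np.maximum(
        1, np.rint(rng.lognormal(_SIZE_MU, _SIZE_SIGMA, size=n_families)).astype(int)
    )
    probs = np.minimum(1.0, global_p * factors)
    counts = rng.binomial(sizes, probs)
    n_orders = max(1, n_families // 10)
    width = max(4, len(str(n_families)))
    return [
        FamilyRecord(
            family=f"family{i + 1:0{width}d}",
            order=f"order{(i % n_orders) + 1:03d}",
            n_species=int(sizes[i]),
            k_halophytes=int(counts[i]),
        )
        for i in range(n_families)
    ]


_GENERA = [
    "Atriplex", "Limonium", "Spartina", "Suaeda", "Tamarix", "Salicornia",
    "Puccinellia", "Avicennia", "Frankenia", "Distichlis",
]
_EPITHETS = [
    "halimus", "vulgare", "maritima", "patula", "chinensis", "europaea",
    "distans", "marina", "salsa", "spicata",
]
_BAD_TOKENS = ["af", "aff", "cf", "sp", "aff.", "cf.", "sp."]


def generate_dirty_tip_names(n: int, seed: int) -> list[tuple[str, bool]]:
    """Names mixing clean binomials with filterable ones; returns (name, keep).

    Roughly half the names are clean binomials or trinomials (keep=True);
    the rest carry indeterminate epithet tokens or hybrid formats
    (keep=False), providing ground truth for the tip-name filter.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    out: list[tuple[str, bool]] = []
    for i in range(n):
        genus = _GENERA[int(rng.integers(len(_GENERA)))]
        ep1 = _EPITHETS[int(rng.integers(len(_EPITHETS)))]
        ep2 = _EPITHETS[int(rng.integers(len(_EPITHETS)))]
        kind = int(rng.integers(6))
        if kind <= 1:
            out.append((f"{genus}_{ep1}", True))
        elif kind == 2:
            out.append((f"{genus}_{ep1}_subsp_{ep2}", True))
        elif kind == 3:
            bad = _BAD_TOKENS[int(rng.integers(len(_BAD_TOKENS)))]
            out.append((f"{genus}_{bad}", False))
        elif kind == 4:
            out.append((f"{genus}_{ep1}_x_{ep2}", False))
        else:
            out.append((f"{genus}_{ep1}_hybrid", False))
    return out
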