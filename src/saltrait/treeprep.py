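"""Turn a large phylogeny plus taxonomy tables into clean family subtrees.

The metric stage needs, per family: a rooted, fully bifurcating subtree
with every branch length equal to 1, tips restricted to determinate
non-hybrid names, and a 0/1 salt-tolerance state for every tip. The
operations here perform that preparation:

* :func:`extract_family_subtree` — clade of the family's tips (MRCA-based
  when the family is not monophyletic, with intruders pruned and logged);
* :func:`filter_tip_names` — drop tips with indeterminate epithets
  (``af``/``aff``/``cf``/``sp``) or hybrid-format labels;
* :func:`resolve_polytomies` — seeded random resolution to a binary tree,
  then all branch lengths set to 1;
* :func:`match_halophytes` — exact name matching (separator- and
  case-normalised only, no fuzzy matching) against a halophyte list.
"""

from __future__ import annotations

import random
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import dendropy

__all__ = [
    "DroppedName",
    "SubtreeLog",
    "extract_family_subtree",
    "filter_tip_names",
    "resolve_polytomies",
    "set_unit_branch_lengths",
    "match_halophytes",
    "normalize_name",
]

_INDETERMINATE = {"af", "aff", "cf", "sp"}


@dataclass(frozen=True)
class DroppedName:
    name: str
    reason: str  # "epithet" | "hybrid"


@dataclass
class SubtreeLog:
    family: str
    removed_intruders: list = field(default_factory=list)


def _tokens(name: str) -> list[str]:
    return [t for t in re.split(r"[\s_]+", name.strip()) if t]


def _drop_reason(name: str) -> str | None:
    toks = [t.lower().rstrip(".") for t in _tokens(name)]
    if any(t in _INDETERMINATE for t in toks):
        return "epithet"
    if "hybrid" in toks:
        return "hybrid"
    # genus + two specific epithets separated by the token "x":
    # an internal "x" with at least two tokens before it and one after
    for i, t in enumerate(toks):
        if t == "x" and i >= 2 and i < len(toks) - 1:
            return "hybrid"
    return None


def filter_tip_names(names: Iterable[str]) -> tuple[list[str], list[DroppedName]]:
    """Split names into (kept, dropped-with-reason).

    A name is dropped iff an underscore/space-delimited token equals one of
    ``af``, ``aff``, ``cf``, ``sp`` (case-insensitive, optional trailing
    period) — token match, never substring, so e.g. Spartina survives — or
    it matches the hybrid patterns (token ``hybrid``, or two epithets
    separated by the token ``x``).
    """
    kept: list[str] = []
    dropped: list[DroppedName] = []
    for name in names:
        reason = _drop_reason(name)
        if reason is None:
            kept.append(name)
        else:
            dropped.append(DroppedName(name=name, reason=reason))
    return kept, dropped


def _taxa_by_label(tree: dendropy.Tree) -> dict:
    return {t.label: t for t in tree.taxon_namespace if t.label is not None}


def extract_family_subtree(
    tree: dendropy.Tree,
    tip_family: Mapping[str, str],
    family: str,
) -> tuple[dendropy.Tree, SubtreeLog]:
    """Extract the clade containing a family's tips.

    If the family is monophyletic the clade is returned as-is; otherwise
    the clade rooted at the family tips' MRCA is taken and out-of-family
    intruder tips are pruned (their names recorded in the log). Degree-2
    nodes left by pruning are suppressed.
    """
    families = set(tip_family.values())
    if family not in families:
        raise KeyError(f"family {family!r} absent from the tip-family table")
    wanted = {tip for tip, fam in tip_family.items() if fam == family}
    by_label = _taxa_by_label(tree)
    present = [by_label[t] for t in wanted if t in by_label]
    if len(present) < 2:
        raise ValueError(
            f"family {family!r} has {len(present)} tips in the tree; need >= 2"
        )
    mrca = tree.mrca(taxa=present)
    clade = dendropy.Tree(seed_node=mrca.extract_subtree())
    clade.is_rooted = True
    clade.update_taxon_namespace()
    clade_tips = {lf.taxon.label for lf in clade.leaf_node_iter()}
    intruders = sorted(clade_tips - wanted)
    log = SubtreeLog(family=family, removed_intruders=intruders)
    if intruders:
        keep = [t for t in clade.taxon_namespace if t.label not in set(intruders)]
        clade.retain_taxa(keep)
        clade.update_taxon_namespace()
    return clade, log


def set_unit_branch_lengths(tree: dendropy.Tree) -> dendropy.Tree:
    """Overwrite every branch length with 1 (equal-branch-length convention)."""
    for edge in tree.preorder_edge_iter():
        edge.length = 1.0
    return tree


def resolve_polytomies(tree: dendropy.Tree, seed: int) -> dendropy.Tree:
    """Randomly resolve all polytomies (seeded) and set branch lengths to 1.

    Operates on a deep copy; the input tree is left untouched. The tip
    label multiset is preserved and the result is fully bifurcating.
    """
    out = tree.clone(depth=1)
    out.resolve_polytomies(rng=random.Random(seed))
    set_unit_branch_lengths(out)
    return out


def normalize_name(name: str) -> str:
    """Case-fold and unify underscore/space separators (single spaces)."""
    return " ".join(_tokens(name)).casefold()


def match_halophytes(
    tips: Sequence[str], halophyte_names: Iterable[str]
) -> dict:
    """0/1 state per tip: 1 iff the normalised tip name is on the list.

    Matching is exact after separator and case normalisation; infraspecific
    tips do not collapse to species (a trinomial tip does not match a
    binomial list entry). Zero matches is a valid outcome.
    """
    listed = {normalize_name(n) for n in halophyte_names}
    if not listed:
        raise ValueError("halophyte name list is empty")
    return {tip: int(normalize_name(tip) in listed) for tip in tips}
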